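"""Real intervals with open/closed bounds, and normalized finite unions of them.

An abnormal range for a vital sign is a finite union of intervals over the
reals; bounds may be +/-infinity and each finite bound carries an explicit
open/closed tag.  Numeric restrictions learned from decision-tree paths use
open bounds (a strict ``< c`` condition maps to the half-line ``(-inf, c)``).

A *region* is the canonical form used everywhere in the package: a tuple of
non-empty intervals, sorted by lower bound, pairwise disjoint and
non-mergeable (overlapping or touching intervals are fused).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = ["Interval", "normalize_region", "region_union", "region_contains",
           "region_equal", "half_line"]


@dataclass(frozen=True)
class Interval:
    """One interval over the reals.

    ``lower``/``upper`` may be ``-inf``/``+inf``; infinite bounds are always
    treated as open regardless of their tag.
    """

    lower: float
    upper: float
    lower_closed: bool = False
    upper_closed: bool = False

    def __post_init__(self) -> None:
        if math.isnan(self.lower) or math.isnan(self.upper):
            raise ValueError("interval bounds must not be NaN")
        # infinite endpoints cannot be attained, force the open tag
        if math.isinf(self.lower) and self.lower_closed:
            object.__setattr__(self, "lower_closed", False)
        if math.isinf(self.upper) and self.upper_closed:
            object.__setattr__(self, "upper_closed", False)

    @property
    def empty(self) -> bool:
        if self.lower > self.upper:
            return True
        if self.lower == self.upper:
            return not (self.lower_closed and self.upper_closed)
        return False

    def contains(self, x: float) -> bool:
        if x < self.lower or x > self.upper:
            return False
        if x == self.lower and not self.lower_closed:
            return False
        if x == self.upper and not self.upper_closed:
            return False
        return True

    def __str__(self) -> str:
        lo = "(" if not self.lower_closed else "["
        hi = ")" if not self.upper_closed else "]"
        return f"{lo}{self.lower}, {self.upper}{hi}"


def half_line(op: str, c: float) -> Interval:
    """Interval denoted by a one-sided comparison with constant ``c``.

    ``<`` / ``<=`` give a left half-line, ``>`` / ``>=`` a right one;
    strictness of the comparison decides the open/closed tag at ``c``.
    """
    if op == "<":
        return Interval(-math.inf, c, False, False)
    if op == "<=":
        return Interval(-math.inf, c, False, True)
    if op == ">":
        return Interval(c, math.inf, False, False)
    if op == ">=":
        return Interval(c, math.inf, True, False)
    raise ValueError(f"unsupported operator for a range: {op!r}")


def _mergeable(a: Interval, b: Interval) -> bool:
    """True if a and b (a.lower <= b.lower) overlap or touch without a gap."""
    if b.lower < a.upper:
        return True
    if b.lower == a.upper:
        # touching at a point: mergeable unless both sides exclude the point
        return a.upper_closed or b.lower_closed
    return False


def normalize_region(intervals: Iterable[Interval]) -> tuple[Interval, ...]:
    """Canonicalize: drop empties, sort, fuse overlapping/touching intervals."""
    items = sorted(
        (iv for iv in intervals if not iv.empty),
        key=lambda iv: (iv.lower, not iv.lower_closed),
    )
    out: list[Interval] = []
    for iv in items:
        if out and _mergeable(out[-1], iv):
            prev = out[-1]
            if iv.upper > prev.upper:
                upper, upper_closed = iv.upper, iv.upper_closed
            elif iv.upper == prev.upper:
                upper, upper_closed = prev.upper, prev.upper_closed or iv.upper_closed
            else:
                upper, upper_closed = prev.upper, prev.upper_closed
            out[-1] = Interval(prev.lower, upper, prev.lower_closed, upper_closed)
        else:
            out.append(iv)
    return tuple(out)


def region_union(a: Iterable[Interval], b: Iterable[Interval]) -> tuple[Interval, ...]:
    return normalize_region([*a, *b])


def region_contains(region: Sequence[Interval], x: float) -> bool:
    return any(iv.contains(x) for iv in region)


def region_equal(a: Sequence[Interval], b: Sequence[Interval]) -> bool:
    return tuple(normalize_region(a)) == tuple(normalize_region(b))
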