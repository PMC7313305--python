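"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written against the *data* of a knowledge base by naive
scanning and exhaustive enumeration, deliberately sharing no code with the
engine's matcher, the interval algebra or the tree learner.
"""

from __future__ import annotations

import itertools
import math

from vitalwatch.engine import (ClassAtom, ComparisonAtom, ConjunctiveRule,
                               PropertyAtom, RangeAtom)

LATEST_PREFIX = "latestResult:"


# ---------------------------------------------------------------------------
# interval membership
# ---------------------------------------------------------------------------

def interval_member(value, interval) -> bool:
    lo_ok = value > interval.lower or (value == interval.lower
                                       and interval.lower_closed)
    hi_ok = value < interval.upper or (value == interval.upper
                                       and interval.upper_closed)
    return lo_ok and hi_ok


def region_member(value, intervals) -> bool:
    return any(interval_member(value, iv) for iv in intervals)


def classify_by_scan(kb, sign_code, value) -> bool:
    for ax in kb.axioms.values():
        if ax.sign_code == sign_code and region_member(value, ax.region):
            return True
    return False


# ---------------------------------------------------------------------------
# exhaustive rule matching
# ---------------------------------------------------------------------------

def all_individuals(kb) -> list[str]:
    inds = [f"patient:{p}" for p in kb.patients]
    inds += [f"platform:{p}" for p in kb.platforms]
    seen_vsigns = set()
    for o in kb.observations():
        inds.append(f"obs:{o.observation_id}")
        inds.append(f"result:{o.observation_id}")
        seen_vsigns.add(f"vsign:{o.patient_id}:{o.sign_code}")
    inds += sorted(seen_vsigns)
    return inds


def _result_obs(kb, individual):
    if not individual.startswith("result:"):
        return None
    try:
        return kb.get_observation(individual[len("result:"):])
    except Exception:
        return None


def _latest_pairs(kb, sign, window):
    """(patient individual, result individual) pairs by direct scan."""
    pairs = set()
    for pid in kb.patients:
        mine = [o for o in kb.observations() if o.patient_id == pid]
        if not mine:
            continue
        anchor = max(o.timestamp for o in mine)
        of_sign = [o for o in mine if o.sign_code == sign]
        if not of_sign:
            continue
        best = max(of_sign, key=lambda o: (o.timestamp, o.observation_id))
        if (anchor - best.timestamp).total_seconds() <= window:
            pairs.add((f"patient:{pid}", f"result:{best.observation_id}"))
    return pairs


def atom_holds(kb, atom, binding, window) -> bool:
    if isinstance(atom, ClassAtom):
        ind = binding[atom.variable]
        name = atom.class_name
        if name == "Patient":
            return ind.startswith("patient:")
        if name == "Platform":
            return ind.startswith("platform:")
        if name == "Observation":
            return ind.startswith("obs:")
        if name == "Result":
            return ind.startswith("result:")
        if name == "VitalSign":
            return ind.startswith("vsign:")
        ax = kb.axioms.get(name)
        if ax is not None:
            o = _result_obs(kb, ind)
            return (o is not None and o.sign_code == ax.sign_code
                    and isinstance(o.value, float)
                    and region_member(o.value, ax.region))
        return ind in kb.derived.get(name, set())
    if isinstance(atom, PropertyAtom):
        s, o = binding[atom.subject], binding[atom.object]
        name = atom.property_name
        if name == "hasResult":
            return s.startswith("obs:") and o == "result:" + s[len("obs:"):]
        if name == "VitalSignhasObservation":
            if not (s.startswith("vsign:") and o.startswith("obs:")):
                return False
            obs = _result_obs(kb, "result:" + o[len("obs:"):])
            return obs is not None and s == f"vsign:{obs.patient_id}:{obs.sign_code}"
        if name == "hasPatient":
            if not s.startswith("obs:"):
                return False
            obs = _result_obs(kb, "result:" + s[len("obs:"):])
            return obs is not None and o == f"patient:{obs.patient_id}"
        if name == "hasPlatform":
            pl = kb.platforms.get(o[len("platform:"):]) \
                if o.startswith("platform:") else None
            return pl is not None and s == f"patient:{pl.owner}"
        if name.startswith(LATEST_PREFIX):
            sign = name[len(LATEST_PREFIX):]
            return (s, o) in _latest_pairs(kb, sign, window)
        raise AssertionError(f"oracle does not know property {name}")
    if isinstance(atom, RangeAtom):
        o = _result_obs(kb, binding[atom.variable])
        if o is None or not isinstance(o.value, float):
            return False
        ref = atom.reference
        if ref is None or ref == "AbnormalRange":
            return classify_by_scan(kb, o.sign_code, o.value)
        ax = kb.axioms.get(ref)
        if ax is not None:
            return (o.sign_code == ax.sign_code
                    and region_member(o.value, ax.region))
        return o.sign_code == ref and classify_by_scan(kb, ref, o.value)
    if isinstance(atom, ComparisonAtom):
        o = _result_obs(kb, binding[atom.variable])
        if o is None or not isinstance(o.value, float):
            return False
        v, c = o.value, atom.constant
        return {"<": v < c, "<=": v <= c, ">": v > c,
                ">=": v >= c, "=": v == c}[atom.op]
    raise AssertionError(f"unknown atom {atom!r}")


def enumerate_bindings(kb, rule: ConjunctiveRule) -> set[frozenset]:
    """All satisfying assignments by exhaustive product enumeration."""
    variables = sorted(rule.variables())
    individuals = all_individuals(kb)
    out = set()
    for combo in itertools.product(individuals, repeat=len(variables)):
        binding = dict(zip(variables, combo))
        if all(atom_holds(kb, a, binding, rule.co_window)
               for a in rule.antecedent):
            out.add(frozenset(binding.items()))
    return out
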