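"""Closing the loop: alarm history -> tree -> new rules and axioms.

The learning engine builds a labelled instance table from the alert log,
grows and prunes a decision tree, extracts sufficiently supported and pure
emergency paths, and converts each accepted path into

* a conjunctive alarm rule carrying the alarm label (exact conjunction
  semantics, evaluated over the patient's co-occurring latest values), and
* one abnormal-range axiom per path condition (``Perf < 0.5`` becomes class
  ``PerfAN`` with region ``(-inf, 0.5)``), so the generic
  abnormal-vital-sign rule starts firing on the newly learned regions.

Both artifacts are tagged ``provenance="learned"`` and installed through
the knowledge base's public upsert operations; axiom updates are unions, so
repeated learning on unchanged history is idempotent.  Every run is fully
described by a :class:`LearningReport`.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from typing import Optional

from .engine import (ConjunctiveRule, EmitAlert, conditions_rule_id,
                     emergency_rule_from_conditions, rule_conditions)
from .errors import ConfigError
from .intervals import half_line, normalize_region
from .model import AbnormalRangeAxiom, KnowledgeBase, axiom_class_name
from .prep import NORMAL_LABEL, build_training_set
from .tree import (DecisionTree, TreeParams, TreePath, extract_paths,
                   learn_tree)

__all__ = ["LearnParams", "LearningReport", "path_to_rule",
           "conditions_to_axioms", "learn_and_update"]


@dataclass(frozen=True)
class LearnParams:
    """Knobs of one learning run; all defaults are logged in the report."""

    window: float = 60.0
    negative_ratio: float = 1.0
    negative_exclusion: float = 600.0
    min_support: int = 30
    min_purity: float = 0.95
    tree: TreeParams = TreeParams()
    seed: int = 0


@dataclass
class LearningReport:
    """Audit trail of one learning run."""

    run_at: str
    params: dict
    instance_counts: dict[str, int] = field(default_factory=dict)
    tree_size: int = 0
    tree_depth: int = 0
    accepted_paths: list[dict] = field(default_factory=list)
    rejected_paths: list[dict] = field(default_factory=list)
    new_rule_ids: list[str] = field(default_factory=list)
    touched_axioms: list[str] = field(default_factory=list)
    message: str = ""

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)

    def to_text(self) -> str:
        lines = [f"learning run at {self.run_at}",
                 f"instances: {self.instance_counts}",
                 f"tree: {self.tree_size} nodes, depth {self.tree_depth}",
                 f"accepted paths: {len(self.accepted_paths)}",
                 f"rejected paths: {len(self.rejected_paths)}",
                 f"new rules: {', '.join(self.new_rule_ids) or '(none)'}",
                 f"touched axioms: {', '.join(self.touched_axioms) or '(none)'}"]
        if self.message:
            lines.append(self.message)
        return "\n".join(lines)


def path_to_rule(path: TreePath, label: Optional[str] = None,
                 *, co_window: float = 60.0) -> ConjunctiveRule:
    """Turn a tree path into a learned conjunctive alarm rule.

    Only real-valued threshold conditions are supported; a path containing
    a nominal-equality condition is rejected (the alarm-rule language has
    no nominal atoms).
    """
    if not path.conditions:
        raise ConfigError("cannot build a rule from an empty path")
    conds = []
    for attr, op, c in path.conditions:
        if op not in ("<", "<=", ">", ">="):
            raise ConfigError(
                f"path condition {attr} {op} {c!r} is not a real-valued "
                "threshold; nominal conditions are unsupported")
        conds.append((attr, op, float(c)))
    label = label or path.label
    return emergency_rule_from_conditions(label, conds,
                                          provenance="learned",
                                          co_window=co_window)


def conditions_to_axioms(rule: ConjunctiveRule,
                         created_at: Optional[_dt.datetime] = None
                         ) -> list[AbnormalRangeAxiom]:
    """Per-sign abnormal-range axioms from a conjunctive alarm rule.

    Each threshold condition becomes one axiom: ``sign < c`` maps to class
    ``<sign>AN`` with the open half-line ``(-inf, c)`` (strict operators
    give open bounds, non-strict give closed ones).  Conditions on the same
    sign merge into a single axiom whose region is their union.  Equality
    conditions are rejected: a single point is not a range.
    """
    conds = rule_conditions(rule)
    if conds is None:
        raise ConfigError(
            f"rule {rule.rule_id!r} has no threshold conditions to convert")
    by_sign: dict[str, list] = {}
    for sign, op, c in conds:
        if op == "=":
            raise ConfigError(
                f"equality condition on {sign} cannot define a range")
        by_sign.setdefault(sign, []).append(half_line(op, c))
    out = []
    for sign in dict.fromkeys(s for s, _o, _c in conds):
        out.append(AbnormalRangeAxiom(
            class_name=axiom_class_name(sign),
            sign_code=sign,
            region=normalize_region(by_sign[sign]),
            provenance="learned",
            created_at=created_at))
    return out


def learn_and_update(kb: KnowledgeBase,
                     params: LearnParams = LearnParams(),
                     *,
                     dry_run: bool = False
                     ) -> tuple[KnowledgeBase, LearningReport]:
    """One pass of the learning loop over the current alarm history.

    Builds the training set, learns and prunes a tree, extracts non-NORMAL
    paths meeting the support/purity thresholds, converts them to rules and
    axioms, and upserts both (unless ``dry_run``).  Deterministic given the
    KB and the seed; timestamps in learned artifacts use the KB's latest
    event time so repeated runs are byte-reproducible.
    """
    now = kb.latest_event_time() or _dt.datetime(1970, 1, 1,
                                                 tzinfo=_dt.timezone.utc)
    report = LearningReport(
        run_at=now.isoformat(),
        params={"window": params.window,
                "negative_ratio": params.negative_ratio,
                "negative_exclusion": params.negative_exclusion,
                "min_support": params.min_support,
                "min_purity": params.min_purity,
                "min_leaf": params.tree.min_leaf,
                "max_depth": params.tree.max_depth,
                "prune_fraction": params.tree.prune_fraction,
                "seed": params.seed})

    table = build_training_set(kb, params.window,
                               negative_ratio=params.negative_ratio,
                               negative_exclusion=params.negative_exclusion,
                               seed=params.seed)
    counts = table.labels.value_counts().to_dict() if len(table) else {}
    report.instance_counts = {str(k): int(v) for k, v in counts.items()}
    n_pos = sum(v for k, v in report.instance_counts.items()
                if k != NORMAL_LABEL)
    if n_pos == 0:
        report.message = "no positive instances in the alert log; no-op"
        return kb, report

    tree_params = TreeParams(min_leaf=params.tree.min_leaf,
                             max_depth=params.tree.max_depth,
                             prune_fraction=params.tree.prune_fraction,
                             seed=params.seed)
    tree = learn_tree(table, tree_params)
    report.tree_size = tree.n_nodes
    report.tree_depth = tree.depth

    alarm_labels = {l for l in tree.labels if l != NORMAL_LABEL}
    candidates = extract_paths(tree, label_filter=alarm_labels)
    accepted: list[TreePath] = []
    for path in candidates:
        entry = {"label": path.label, "support": path.support,
                 "purity": round(path.purity, 6),
                 "conditions": [[a, o, c] for a, o, c in path.conditions]}
        if path.support < params.min_support:
            entry["reason"] = f"support {path.support} < {params.min_support}"
            report.rejected_paths.append(entry)
            continue
        if path.purity < params.min_purity:
            entry["reason"] = f"purity {path.purity:.3f} < {params.min_purity}"
            report.rejected_paths.append(entry)
            continue
        if any(op == "=" for _a, op, _c in path.conditions):
            entry["reason"] = "nominal conditions unsupported in alarm rules"
            report.rejected_paths.append(entry)
            continue
        accepted.append(path)
        report.accepted_paths.append(entry)

    for path in accepted:
        rule = path_to_rule(path, co_window=params.window)
        axioms = conditions_to_axioms(rule, created_at=now)
        report.new_rule_ids.append(rule.rule_id)
        report.touched_axioms.extend(a.class_name for a in axioms)
        if not dry_run:
            if rule.rule_id in kb.rules:
                del kb.rules[rule.rule_id]
            kb.add_rule(rule)
            for ax in axioms:
                kb.upsert_abnormal_range(ax)
    report.touched_axioms = sorted(set(report.touched_axioms))
    if not accepted:
        report.message = "no path met the support/purity thresholds"
    return kb, report
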