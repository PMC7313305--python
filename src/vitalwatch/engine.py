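"""Conjunctive (SWRL-style) rules and the forward-chaining reasoner.

The rule language is the Horn fragment the monitoring loop needs: class
atoms, property atoms, abnormal-range atoms and numeric comparison atoms in
the antecedent; a class assertion or an alarm emission as the consequent.
Negation, disjunction and built-ins beyond numeric comparison are excluded.

Two evaluation modes are provided:

* :func:`apply_all` — batch forward chaining over the whole knowledge base
  to a fixpoint.  Rules create no new individuals, so the fixpoint exists
  and is independent of rule ordering.
* :func:`monitor_stream` — incremental evaluation while ingesting a stream
  of observations in time order, with edge-triggered alarms (an alert fires
  when a rule's predicate becomes true for a patient and is not repeated
  until it has become false again).  This is how a bedside monitor behaves
  and is observationally a deduplicated view of repeated batch evaluation.

The generic rule ``GM`` (:func:`gm_rule`) derives ``AbnormalVitalSign(?v)``
for any vital sign whose observation result lies in a declared abnormal
range; the per-sign abnormal-range classes (``PerfAN`` etc.) act as
sub-regions whose union the generic ``AbnormalRange`` atom tests.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import math
import re
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Iterator, Optional, Sequence, Union

from .errors import ConfigError, DataError, DuplicateError, NominalValueError
from .model import Alert, KnowledgeBase, Observation

__all__ = [
    "ClassAtom", "PropertyAtom", "RangeAtom", "ComparisonAtom", "RuleAtom",
    "AssertClass", "EmitAlert", "ConjunctiveRule",
    "gm_rule", "abnormal_alert_rule", "match_rule", "apply_all",
    "emergency_rule_from_conditions", "parse_condition_text",
    "monitor_stream", "alerts_to_jsonl", "alerts_from_jsonl",
    "rule_to_json", "rule_from_json", "rule_to_swrl", "rule_from_swrl",
]

_COMPARISON_OPS = {"<", "<=", ">", ">=", "="}
_LATEST_PREFIX = "latestResult:"

GM_RULE_ID = "GM"
GENERIC_ALERT_RULE_ID = "GM-alert"
GENERIC_ALERT_LABEL = "ABNORMAL VITAL SIGN"


# ---------------------------------------------------------------------------
# rule syntax
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassAtom:
    class_name: str
    variable: str


@dataclass(frozen=True)
class PropertyAtom:
    property_name: str
    subject: str
    object: str


@dataclass(frozen=True)
class RangeAtom:
    """Abnormal-range membership of a result's value.

    ``reference`` is ``None`` for the generic ``AbnormalRange`` class (union
    of all declared abnormal regions for the result's sign), an axiom class
    name (e.g. ``PerfAN``), or a sign code (union of that sign's axioms).
    """

    reference: Optional[str]
    variable: str


@dataclass(frozen=True)
class ComparisonAtom:
    variable: str
    op: str
    constant: float

    def __post_init__(self) -> None:
        if self.op not in _COMPARISON_OPS:
            raise ConfigError(f"unsupported comparison operator {self.op!r}")
        if not math.isfinite(self.constant):
            raise ConfigError("comparison constants must be finite reals")


RuleAtom = Union[ClassAtom, PropertyAtom, RangeAtom, ComparisonAtom]


@dataclass(frozen=True)
class AssertClass:
    class_name: str
    variable: str


@dataclass(frozen=True)
class EmitAlert:
    label: str


@dataclass
class ConjunctiveRule:
    """A safe Horn rule: conjunction of atoms -> class assertion or alarm."""

    rule_id: str
    antecedent: tuple[RuleAtom, ...]
    consequent: Union[AssertClass, EmitAlert]
    label: Optional[str] = None
    provenance: str = "manual"
    enabled: bool = True
    #: co-occurrence window (seconds) for latest-observation bindings
    co_window: float = 60.0

    def variables(self) -> set[str]:
        out: set[str] = set()
        for atom in self.antecedent:
            if isinstance(atom, ClassAtom):
                out.add(atom.variable)
            elif isinstance(atom, PropertyAtom):
                out.update((atom.subject, atom.object))
            elif isinstance(atom, (RangeAtom, ComparisonAtom)):
                out.add(atom.variable)
        return out

    def validate(self) -> None:
        """Safety: non-empty antecedent, consequent variables all bound."""
        if not self.antecedent:
            raise ConfigError(f"rule {self.rule_id!r} has an empty antecedent")
        if isinstance(self.consequent, AssertClass):
            if self.consequent.variable not in self.variables():
                raise ConfigError(
                    f"rule {self.rule_id!r} is unsafe: consequent variable "
                    f"{self.consequent.variable!r} not bound in the antecedent")
        if self.provenance not in ("seed", "learned", "manual"):
            raise ConfigError("rule provenance must be seed/learned/manual")

    # -- JSON -------------------------------------------------------------

    def to_dict(self) -> dict:
        def atom_d(a: RuleAtom) -> dict:
            if isinstance(a, ClassAtom):
                return {"kind": "class", "class_name": a.class_name,
                        "variable": a.variable}
            if isinstance(a, PropertyAtom):
                return {"kind": "property", "property_name": a.property_name,
                        "subject": a.subject, "object": a.object}
            if isinstance(a, RangeAtom):
                return {"kind": "range", "reference": a.reference,
                        "variable": a.variable}
            return {"kind": "comparison", "variable": a.variable,
                    "op": a.op, "constant": a.constant}

        if isinstance(self.consequent, AssertClass):
            cons = {"kind": "assert_class",
                    "class_name": self.consequent.class_name,
                    "variable": self.consequent.variable}
        else:
            cons = {"kind": "emit_alert", "label": self.consequent.label}
        return {"rule_id": self.rule_id, "label": self.label,
                "antecedent": [atom_d(a) for a in self.antecedent],
                "consequent": cons, "provenance": self.provenance,
                "enabled": self.enabled, "co_window": self.co_window}

    @classmethod
    def from_dict(cls, d: dict) -> "ConjunctiveRule":
        def atom(a: dict) -> RuleAtom:
            k = a["kind"]
            if k == "class":
                return ClassAtom(a["class_name"], a["variable"])
            if k == "property":
                return PropertyAtom(a["property_name"], a["subject"], a["object"])
            if k == "range":
                return RangeAtom(a["reference"], a["variable"])
            if k == "comparison":
                return ComparisonAtom(a["variable"], a["op"], float(a["constant"]))
            raise DataError(f"unknown atom kind {k!r} in rule JSON")

        c = d["consequent"]
        if c["kind"] == "assert_class":
            cons: Union[AssertClass, EmitAlert] = AssertClass(
                c["class_name"], c["variable"])
        elif c["kind"] == "emit_alert":
            cons = EmitAlert(c["label"])
        else:
            raise DataError(f"unknown consequent kind {c['kind']!r}")
        rule = cls(rule_id=d["rule_id"],
                   antecedent=tuple(atom(a) for a in d["antecedent"]),
                   consequent=cons,
                   label=d.get("label"),
                   provenance=d.get("provenance", "manual"),
                   enabled=d.get("enabled", True),
                   co_window=float(d.get("co_window", 60.0)))
        rule.validate()
        return rule


def rule_to_json(rule: ConjunctiveRule) -> str:
    return json.dumps(rule.to_dict(), indent=2, sort_keys=True)


def rule_from_json(text: str) -> ConjunctiveRule:
    return ConjunctiveRule.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# SWRL-like text form
# ---------------------------------------------------------------------------

#: borrowed vocabularies are name-compatible only; these prefixes are purely
#: presentational in the text form
_CLASS_PREFIX = {"VitalSign": "icnp", "Result": "icnp", "Patient": "icnp",
                 "Observation": "sosa", "Platform": "ssn"}
_PROP_PREFIX = {"hasResult": "sosa"}
_OP_TO_SWRLB = {"<": "lessThan", "<=": "lessThanOrEqual", ">": "greaterThan",
                ">=": "greaterThanOrEqual", "=": "equal"}
_SWRLB_TO_OP = {v: k for k, v in _OP_TO_SWRLB.items()}


def _atom_to_text(atom: RuleAtom) -> str:
    if isinstance(atom, ClassAtom):
        pfx = _CLASS_PREFIX.get(atom.class_name)
        name = f"{pfx}:{atom.class_name}" if pfx else atom.class_name
        return f"{name}({atom.variable})"
    if isinstance(atom, PropertyAtom):
        if atom.property_name.startswith(_LATEST_PREFIX):
            name = "latestResult_" + atom.property_name[len(_LATEST_PREFIX):]
        else:
            pfx = _PROP_PREFIX.get(atom.property_name)
            name = (f"{pfx}:{atom.property_name}" if pfx
                    else atom.property_name)
        return f"{name}({atom.subject}, {atom.object})"
    if isinstance(atom, RangeAtom):
        name = atom.reference if atom.reference else "AbnormalRange"
        return f"{name}({atom.variable})"
    return (f"swrlb:{_OP_TO_SWRLB[atom.op]}({atom.variable}, "
            f"{atom.constant:g})")


def rule_to_swrl(rule: ConjunctiveRule) -> str:
    """Human-readable SWRL-like rendering, e.g. the generic rule::

        icnp:VitalSign(?v) ^ sosa:Observation(?o) ^ ... -> AbnormalVitalSign(?v)
    """
    body = " ^ ".join(_atom_to_text(a) for a in rule.antecedent)
    if isinstance(rule.consequent, AssertClass):
        head = f"{rule.consequent.class_name}({rule.consequent.variable})"
    else:
        head = f'alert("{rule.consequent.label}")'
    return f"{body} -> {head}"


_ATOM_RE = re.compile(r"\s*([A-Za-z_][\w:]*)\(([^)]*)\)\s*$")


def rule_from_swrl(text: str, *, rule_id: str, label: Optional[str] = None,
                   provenance: str = "manual",
                   co_window: float = 60.0) -> ConjunctiveRule:
    """Parse the SWRL-like text form back into a rule.

    Identity metadata (id, label, provenance, window) is not part of the
    text form and is supplied by the caller.
    """
    try:
        body_text, head_text = text.split("->")
    except ValueError:
        raise DataError(f"rule text must contain a single '->': {text!r}")

    def parse_atom(tok: str) -> RuleAtom:
        m = _ATOM_RE.match(tok)
        if not m:
            raise DataError(f"cannot parse rule atom {tok!r}")
        name, args_text = m.group(1), m.group(2)
        args = [a.strip() for a in args_text.split(",")]
        bare = name.split(":", 1)[-1]
        if name.startswith("swrlb:"):
            if bare not in _SWRLB_TO_OP or len(args) != 2:
                raise DataError(f"cannot parse comparison atom {tok!r}")
            return ComparisonAtom(args[0], _SWRLB_TO_OP[bare], float(args[1]))
        if name.startswith("latestResult_"):
            sign = name[len("latestResult_"):]
            if len(args) != 2:
                raise DataError(f"latestResult atom needs two arguments: {tok!r}")
            return PropertyAtom(_LATEST_PREFIX + sign, args[0], args[1])
        if len(args) == 2:
            return PropertyAtom(bare, args[0], args[1])
        if bare == "AbnormalRange":
            return RangeAtom(None, args[0])
        if bare.endswith("AN"):
            return RangeAtom(bare, args[0])
        return ClassAtom(bare, args[0])

    antecedent = tuple(parse_atom(t) for t in body_text.split("^"))
    head = head_text.strip()
    m = re.match(r'alert\("(.*)"\)$', head)
    if m:
        cons: Union[AssertClass, EmitAlert] = EmitAlert(m.group(1))
        label = label or m.group(1)
    else:
        hm = _ATOM_RE.match(head)
        if not hm:
            raise DataError(f"cannot parse rule head {head!r}")
        args = [a.strip() for a in hm.group(2).split(",")]
        cons = AssertClass(hm.group(1).split(":", 1)[-1], args[0])
    rule = ConjunctiveRule(rule_id=rule_id, antecedent=antecedent,
                           consequent=cons, label=label,
                           provenance=provenance, co_window=co_window)
    rule.validate()
    return rule


# ---------------------------------------------------------------------------
# fixed rules
# ---------------------------------------------------------------------------

def gm_rule() -> ConjunctiveRule:
    """The generic abnormal-vital-sign rule.

    For a vital sign ?v with observation ?o whose result ?r lies in an
    abnormal range, ?v is an abnormal vital sign::

        icnp:VitalSign(?v) ^ sosa:Observation(?o) ^
        VitalSignhasObservation(?v, ?o) ^ icnp:Result(?r) ^
        sosa:hasResult(?o, ?r) ^ AbnormalRange(?r) -> AbnormalVitalSign(?v)
    """
    return ConjunctiveRule(
        rule_id=GM_RULE_ID,
        antecedent=(
            ClassAtom("VitalSign", "?v"),
            ClassAtom("Observation", "?o"),
            PropertyAtom("VitalSignhasObservation", "?v", "?o"),
            ClassAtom("Result", "?r"),
            PropertyAtom("hasResult", "?o", "?r"),
            RangeAtom(None, "?r"),
        ),
        consequent=AssertClass("AbnormalVitalSign", "?v"),
        provenance="seed",
    )


def abnormal_alert_rule() -> ConjunctiveRule:
    """Companion alarm rule: any derived AbnormalVitalSign raises a generic alert."""
    return ConjunctiveRule(
        rule_id=GENERIC_ALERT_RULE_ID,
        antecedent=(
            ClassAtom("AbnormalVitalSign", "?v"),
            ClassAtom("Observation", "?o"),
            PropertyAtom("VitalSignhasObservation", "?v", "?o"),
            ClassAtom("Result", "?r"),
            PropertyAtom("hasResult", "?o", "?r"),
            RangeAtom(None, "?r"),
        ),
        consequent=EmitAlert(GENERIC_ALERT_LABEL),
        label=GENERIC_ALERT_LABEL,
        provenance="seed",
    )


# ---------------------------------------------------------------------------
# emergency rules from threshold conditions
# ---------------------------------------------------------------------------

Condition = tuple[str, str, float]


def _slug(text: str) -> str:
    return re.sub(r"[^A-Za-z0-9]+", "-", text).strip("-").lower() or "rule"


def conditions_rule_id(label: str, conditions: Sequence[Condition]) -> str:
    """Deterministic, content-addressed id for a learned/authored alarm rule."""
    digest = hashlib.sha1(
        json.dumps(sorted(conditions)).encode()).hexdigest()[:8]
    return f"{_slug(label)}-{digest}"


def emergency_rule_from_conditions(label: str,
                                   conditions: Sequence[Condition],
                                   *,
                                   rule_id: Optional[str] = None,
                                   provenance: str = "manual",
                                   co_window: float = 60.0) -> ConjunctiveRule:
    """Conjunctive alarm rule over the patient's most recent observations.

    Each condition ``(sign, op, constant)`` constrains the patient's latest
    observation of that sign; all latest observations must co-occur within
    ``co_window`` seconds of the patient's most recent measurement.  Two
    conditions over the same sign constrain the same bound observation.
    """
    if not conditions:
        raise ConfigError("an emergency rule needs at least one condition")
    atoms: list[RuleAtom] = [ClassAtom("Patient", "?p")]
    seen_signs: list[str] = []
    for sign, op, _c in conditions:
        if not sign:
            raise ConfigError("condition sign code must be non-empty")
        if op not in ("<", "<=", ">", ">="):
            raise ConfigError(
                f"emergency conditions use one-sided comparisons, got {op!r}")
        if sign not in seen_signs:
            seen_signs.append(sign)
    for sign in seen_signs:
        atoms.append(PropertyAtom(_LATEST_PREFIX + sign, "?p", f"?r_{sign}"))
    for sign, op, c in conditions:
        atoms.append(ComparisonAtom(f"?r_{sign}", op, float(c)))
    rule = ConjunctiveRule(
        rule_id=rule_id or conditions_rule_id(label, conditions),
        antecedent=tuple(atoms),
        consequent=EmitAlert(label),
        label=label,
        provenance=provenance,
        co_window=co_window,
    )
    rule.validate()
    return rule


def rule_conditions(rule: ConjunctiveRule) -> Optional[list[Condition]]:
    """Recover (sign, op, constant) conditions from an emergency-shaped rule.

    Returns ``None`` for rules that are not of the latest-observation alarm
    shape (e.g. the generic GM rule).
    """
    if not isinstance(rule.consequent, EmitAlert):
        return None
    var_sign: dict[str, str] = {}
    conditions: list[Condition] = []
    for atom in rule.antecedent:
        if isinstance(atom, PropertyAtom) and \
                atom.property_name.startswith(_LATEST_PREFIX):
            var_sign[atom.object] = atom.property_name[len(_LATEST_PREFIX):]
    if not var_sign:
        return None
    for atom in rule.antecedent:
        if isinstance(atom, ComparisonAtom):
            sign = var_sign.get(atom.variable)
            if sign is None:
                return None
            conditions.append((sign, atom.op, atom.constant))
    return conditions or None


_COND_TEXT_RE = re.compile(
    r"^\s*([A-Za-z][\w ()]*?)\s*(<=|>=|<|>)\s*([-+0-9.,eE]+)\s*$")


def parse_condition_text(text: str) -> list[Condition]:
    """Parse an ``and``-joined conjunction of threshold conditions.

    Accepts the monitor-log style, e.g.
    ``"Perf < 0.5 and AWV < 3749.05 and AWF < 10.4 and NBP (Sys) < 105"``.
    Sign tokens are canonicalized to catalog codes: a parenthesised
    qualifier becomes an underscore suffix (``NBP (Sys)`` -> ``NBP_Sys``).
    """
    out: list[Condition] = []
    for clause in re.split(r"\band\b", text):
        if not clause.strip():
            continue
        m = _COND_TEXT_RE.match(clause)
        if m is None:
            raise DataError(f"cannot parse condition {clause.strip()!r}")
        sign = re.sub(r"\s*\(\s*", "_", m.group(1).strip())
        sign = sign.replace(")", "").replace(" ", "")
        out.append((sign, m.group(2), float(m.group(3).replace(",", ""))))
    if not out:
        raise DataError("no conditions found in rule text")
    return out


# ---------------------------------------------------------------------------
# ABox view: the individuals and relations the matcher ranges over
# ---------------------------------------------------------------------------

class ABoxView:
    """Materialized individuals of a knowledge base for rule matching.

    Individual ids are namespaced strings: ``patient:<id>``, ``obs:<id>``,
    ``result:<id>`` (one result per observation) and ``vsign:<patient>:<sign>``
    (one vital-sign individual per patient/sign pair with observations).
    """

    def __init__(self, kb: KnowledgeBase):
        self.kb = kb
        self.patient_inds = {f"patient:{p}" for p in kb.patients}
        self.platform_inds = {f"platform:{p}" for p in kb.platforms}
        obs = list(kb.observations())
        self.obs_inds = {f"obs:{o.observation_id}" for o in obs}
        self.result_inds = {f"result:{o.observation_id}" for o in obs}
        self.result_info: dict[str, Observation] = {
            f"result:{o.observation_id}": o for o in obs}
        self.vsign_inds: set[str] = set()
        self._vshas: dict[str, list[str]] = {}
        self._has_result: dict[str, str] = {}
        self._has_patient: dict[str, str] = {}
        self._patient_anchor: dict[str, _dt.datetime] = {}
        for o in obs:
            v = f"vsign:{o.patient_id}:{o.sign_code}"
            self.vsign_inds.add(v)
            self._vshas.setdefault(v, []).append(f"obs:{o.observation_id}")
            self._has_result[f"obs:{o.observation_id}"] = \
                f"result:{o.observation_id}"
            self._has_patient[f"obs:{o.observation_id}"] = \
                f"patient:{o.patient_id}"
            prev = self._patient_anchor.get(o.patient_id)
            if prev is None or o.timestamp > prev:
                self._patient_anchor[o.patient_id] = o.timestamp
        self._has_platform: dict[str, list[str]] = {}
        for pl in kb.platforms.values():
            self._has_platform.setdefault(
                f"patient:{pl.owner}", []).append(f"platform:{pl.platform_id}")
        self._latest_cache: dict[tuple[str, float], dict[str, str]] = {}

    # -- classes ----------------------------------------------------------

    def class_ext(self, name: str) -> set[str]:
        builtin = {"Patient": self.patient_inds,
                   "Observation": self.obs_inds,
                   "Result": self.result_inds,
                   "VitalSign": self.vsign_inds,
                   "Platform": self.platform_inds}
        if name in builtin:
            return builtin[name]
        ax = self.kb.axioms.get(name)
        if ax is not None:
            return {rid for rid, o in self.result_info.items()
                    if o.sign_code == ax.sign_code
                    and isinstance(o.value, float) and ax.contains(o.value)}
        # derived classes; empty extension until forward chaining fills them
        return self.kb.derived.get(name, set())

    # -- properties -------------------------------------------------------

    def property_pairs(self, name: str,
                       window: float) -> dict[str, list[str]]:
        """Adjacency (subject -> objects) of a property extension."""
        if name == "VitalSignhasObservation":
            return self._vshas
        if name == "hasResult":
            return {s: [o] for s, o in self._has_result.items()}
        if name == "hasPatient":
            return {s: [o] for s, o in self._has_patient.items()}
        if name == "hasPlatform":
            return self._has_platform
        if name.startswith(_LATEST_PREFIX):
            sign = name[len(_LATEST_PREFIX):]
            if sign not in self.kb.sign_catalog:
                raise ConfigError(
                    f"latest-observation property refers to unknown sign "
                    f"{sign!r}")
            key = (sign, window)
            cached = self._latest_cache.get(key)
            if cached is None:
                cached = {}
                for pid in self.kb.patients:
                    anchor = self._patient_anchor.get(pid)
                    if anchor is None:
                        continue
                    o = self.kb.latest_observation(pid, sign, at=anchor,
                                                   window=window)
                    if o is not None:
                        cached[f"patient:{pid}"] = \
                            f"result:{o.observation_id}"
                self._latest_cache[key] = cached
            return {s: [o] for s, o in cached.items()}
        raise ConfigError(f"unknown property {name!r} in rule")

    # -- numeric atoms ----------------------------------------------------

    def result_value(self, individual: str) -> Optional[tuple[str, float]]:
        o = self.result_info.get(individual)
        if o is None or not isinstance(o.value, float):
            return None
        return o.sign_code, o.value

    def range_holds(self, reference: Optional[str], individual: str) -> bool:
        sv = self.result_value(individual)
        if sv is None:
            return False
        sign, value = sv
        if reference is None or reference == "AbnormalRange":
            try:
                return self.kb.classify_result(sign, value)
            except NominalValueError:
                return False
        ax = self.kb.axioms.get(reference)
        if ax is not None:
            return ax.sign_code == sign and ax.contains(value)
        if reference in self.kb.sign_catalog:
            return sign == reference and self.kb.classify_result(sign, value)
        raise ConfigError(
            f"range atom refers to unknown class or sign {reference!r}")

    def comparison_holds(self, atom: ComparisonAtom, individual: str) -> bool:
        sv = self.result_value(individual)
        if sv is None:
            return False
        _sign, value = sv
        return {"<": value < atom.constant,
                "<=": value <= atom.constant,
                ">": value > atom.constant,
                ">=": value >= atom.constant,
                "=": value == atom.constant}[atom.op]


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def _atom_vars(atom: RuleAtom) -> tuple[str, ...]:
    if isinstance(atom, PropertyAtom):
        return (atom.subject, atom.object)
    if isinstance(atom, ClassAtom):
        return (atom.variable,)
    return (atom.variable,)


def _atom_cost(atom: RuleAtom, bound: set[str]) -> int:
    """Greedy join-order heuristic; does not affect the result set."""
    unbound = sum(1 for v in _atom_vars(atom) if v not in bound)
    if unbound == 0:
        return 0
    if isinstance(atom, PropertyAtom):
        return 1 if unbound == 1 else 4
    if isinstance(atom, ClassAtom):
        return 2
    return 3  # range/comparison over an unbound variable


def _extend(atom: RuleAtom, binding: dict[str, str], view: ABoxView,
            window: float) -> Iterator[dict[str, str]]:
    if isinstance(atom, ClassAtom):
        ext = view.class_ext(atom.class_name)
        v = binding.get(atom.variable)
        if v is not None:
            if v in ext:
                yield binding
            return
        for ind in sorted(ext):
            yield {**binding, atom.variable: ind}
        return
    if isinstance(atom, PropertyAtom):
        pairs = view.property_pairs(atom.property_name, window)
        s = binding.get(atom.subject)
        o = binding.get(atom.object)
        if s is not None:
            objs = pairs.get(s, [])
            if o is not None:
                if o in objs:
                    yield binding
                return
            for obj in sorted(objs):
                yield {**binding, atom.object: obj}
            return
        for subj in sorted(pairs):
            for obj in sorted(pairs[subj]):
                if o is not None and obj != o:
                    continue
                nb = {**binding, atom.subject: subj}
                if o is None:
                    nb[atom.object] = obj
                yield nb
        return
    if isinstance(atom, RangeAtom):
        v = binding.get(atom.variable)
        if v is not None:
            if view.range_holds(atom.reference, v):
                yield binding
            return
        for ind in sorted(view.result_inds):
            if view.range_holds(atom.reference, ind):
                yield {**binding, atom.variable: ind}
        return
    # ComparisonAtom
    v = binding.get(atom.variable)
    if v is not None:
        if view.comparison_holds(atom, v):
            yield binding
        return
    for ind in sorted(view.result_inds):
        if view.comparison_holds(atom, ind):
            yield {**binding, atom.variable: ind}


def match_rule(kb: KnowledgeBase, rule: ConjunctiveRule,
               view: Optional[ABoxView] = None) -> list[dict[str, str]]:
    """All variable bindings under which every antecedent atom holds.

    Pure query: no side effects on the knowledge base.  The join order is
    chosen greedily for efficiency but the returned set equals exhaustive
    enumeration over all assignments of individuals to variables.
    """
    rule.validate()
    if not rule.enabled:
        return []
    if view is None:
        view = ABoxView(kb)
    remaining = list(rule.antecedent)
    bindings: list[dict[str, str]] = [{}]
    while remaining and bindings:
        bound = set(bindings[0])
        remaining.sort(key=lambda a: _atom_cost(a, bound))
        atom = remaining.pop(0)
        bindings = [nb for b in bindings
                    for nb in _extend(atom, b, view, rule.co_window)]
    return bindings


# ---------------------------------------------------------------------------
# forward chaining
# ---------------------------------------------------------------------------

def _alert_from_binding(kb: KnowledgeBase, rule: ConjunctiveRule,
                        binding: dict[str, str]) -> tuple[str, str, frozenset[str]]:
    """(patient_id, label, evidence observation ids) for an alarm firing."""
    evidence = set()
    patients = set()
    for ind in binding.values():
        if ind.startswith("obs:"):
            evidence.add(ind[len("obs:"):])
        elif ind.startswith("result:"):
            evidence.add(ind[len("result:"):])
        elif ind.startswith("patient:"):
            patients.add(ind[len("patient:"):])
    if not evidence:
        raise DataError(
            f"alarm rule {rule.rule_id!r} fired without observation evidence")
    ev_patients = {kb.get_observation(oid).patient_id for oid in evidence}
    patients |= ev_patients
    if len(patients) != 1:
        raise DataError(
            f"alarm rule {rule.rule_id!r} fired across patients {patients}")
    label = rule.consequent.label  # type: ignore[union-attr]
    return patients.pop(), label, frozenset(evidence)


def apply_all(kb: KnowledgeBase,
              rules: Iterable[ConjunctiveRule]) -> tuple[KnowledgeBase, list[Alert]]:
    """Forward chaining to a fixpoint; returns the KB and new alerts.

    Class-assertion consequents add derived facts; alarm consequents append
    deduplicated alerts (one per distinct (patient, label, evidence) within
    the call).  Rules create no new individuals, so iteration terminates;
    with purely positive rules the fixpoint is order-independent.
    """
    ruleset = sorted((r for r in rules if r.enabled), key=lambda r: r.rule_id)
    for r in ruleset:
        r.validate()
        if r.rule_id not in kb.rules:
            kb.add_rule(r)
    view = ABoxView(kb)
    new_alerts: list[Alert] = []
    # dedup within this call only; cross-call suppression is a policy of the
    # stream monitor, not of batch application
    seen: set[tuple[str, str, frozenset[str]]] = set()
    changed = True
    while changed:
        changed = False
        for rule in ruleset:
            for binding in match_rule(kb, rule, view=view):
                if isinstance(rule.consequent, AssertClass):
                    ind = binding[rule.consequent.variable]
                    if kb.assert_derived(rule.consequent.class_name, ind):
                        changed = True
                else:
                    key = _alert_from_binding(kb, rule, binding)
                    if key in seen:
                        continue
                    seen.add(key)
                    pid, label, evidence = key
                    ts = max(kb.get_observation(o).timestamp for o in evidence)
                    alert = Alert(alert_id=kb.next_alert_id(),
                                  patient_id=pid, timestamp=ts, label=label,
                                  fired_rule_id=rule.rule_id,
                                  evidence=evidence)
                    kb.append_alert(alert)
                    new_alerts.append(alert)
    return kb, new_alerts


# ---------------------------------------------------------------------------
# stream monitoring
# ---------------------------------------------------------------------------

@dataclass
class MonitorResult:
    alerts: list[Alert]
    ingested: int
    duplicates: int


def monitor_stream(kb: KnowledgeBase, observations: Iterable[Observation],
                   rules: Optional[Iterable[ConjunctiveRule]] = None,
                   *, gm_alerts: bool = True) -> MonitorResult:
    """Ingest a stream in time order, firing edge-triggered alarms.

    Two alarm sources run side by side, mirroring batch semantics
    incrementally:

    * the generic rule: an observation whose value is in a declared abnormal
      range derives ``AbnormalVitalSign`` and (with ``gm_alerts``) raises a
      generic per-sign alert on the transition into the abnormal range;
    * installed emergency rules (latest-observation conjunctions): the alarm
      fires when the patient's co-occurring latest values first satisfy all
      conditions, and re-arms once they no longer do.

    Observations already present in the KB (by id) are skipped and counted
    as duplicates, so re-running a file is idempotent.
    """
    if rules is None:
        ruleset = [r for r in kb.rules.values()
                   if isinstance(r, ConjunctiveRule) and r.enabled
                   and isinstance(r.consequent, EmitAlert)]
    else:
        ruleset = [r for r in rules if r.enabled]
        for r in ruleset:
            if r.rule_id not in kb.rules:
                kb.add_rule(r)
    if gm_alerts:
        for fixed in (gm_rule(), abnormal_alert_rule()):
            if fixed.rule_id not in kb.rules:
                kb.add_rule(fixed)
    compiled = []
    for r in ruleset:
        conds = rule_conditions(r)
        if conds is not None:
            signs = {s for s, _op, _c in conds}
            compiled.append((r, conds, signs))
    alerts: list[Alert] = []
    duplicates = 0
    ingested = 0
    # edge-trigger state per (patient, alarm key)
    active: dict[tuple[str, str], bool] = {}
    latest: dict[tuple[str, str], Observation] = {}

    def emit(rule_id: str, label: str, pid: str,
             evidence: frozenset[str], ts: _dt.datetime) -> None:
        alert = Alert(alert_id=kb.next_alert_id(), patient_id=pid,
                      timestamp=ts, label=label, fired_rule_id=rule_id,
                      evidence=evidence)
        kb.append_alert(alert)
        alerts.append(alert)

    ordered = sorted(observations,
                     key=lambda o: (o.timestamp, o.patient_id, o.observation_id))
    for obs in ordered:
        try:
            kb.assert_observation(obs)
        except DuplicateError:
            duplicates += 1
            continue
        ingested += 1
        pid, sign = obs.patient_id, obs.sign_code
        latest[(pid, sign)] = obs
        # generic rule, incremental
        sign_def = kb.sign_catalog[sign]
        if sign_def.value_kind == "real":
            abnormal = kb.classify_result(sign, obs.value)  # type: ignore[arg-type]
            if abnormal:
                kb.assert_derived("AbnormalVitalSign", f"vsign:{pid}:{sign}")
            if gm_alerts:
                key = (pid, f"{GENERIC_ALERT_LABEL}:{sign}")
                if abnormal and not active.get(key, False):
                    emit(GENERIC_ALERT_RULE_ID,
                         f"{GENERIC_ALERT_LABEL} ({sign})",
                         pid, frozenset({obs.observation_id}), obs.timestamp)
                active[key] = abnormal
        # emergency rules touching this sign
        for rule, conds, signs in compiled:
            if sign not in signs:
                continue
            key = (pid, rule.rule_id)
            satisfied = True
            evidence = set()
            for csign, op, const in conds:
                lo = latest.get((pid, csign))
                if lo is None or not isinstance(lo.value, float) or \
                        (obs.timestamp - lo.timestamp).total_seconds() > rule.co_window:
                    satisfied = False
                    break
                ok = {"<": lo.value < const, "<=": lo.value <= const,
                      ">": lo.value > const, ">=": lo.value >= const}[op]
                if not ok:
                    satisfied = False
                    break
                evidence.add(lo.observation_id)
            if satisfied and not active.get(key, False):
                emit(rule.rule_id, rule.consequent.label, pid,
                     frozenset(evidence), obs.timestamp)
            active[key] = satisfied
    return MonitorResult(alerts=alerts, ingested=ingested,
                         duplicates=duplicates)


# ---------------------------------------------------------------------------
# alert persistence
# ---------------------------------------------------------------------------

def alerts_to_jsonl(alerts: Iterable[Alert], fp: IO[str]) -> None:
    for a in sorted(alerts, key=lambda a: (a.timestamp, a.alert_id)):
        fp.write(json.dumps({
            "alert_id": a.alert_id,
            "patient_id": a.patient_id,
            "timestamp": a.timestamp.isoformat(),
            "label": a.label,
            "fired_rule_id": a.fired_rule_id,
            "evidence": sorted(a.evidence),
        }, sort_keys=True) + "\n")


def alerts_from_jsonl(fp: IO[str]) -> list[Alert]:
    out = []
    for line in fp:
        if not line.strip():
            continue
        d = json.loads(line)
        out.append(Alert(alert_id=d["alert_id"], patient_id=d["patient_id"],
                         timestamp=_dt.datetime.fromisoformat(d["timestamp"]),
                         label=d["label"], fired_rule_id=d["fired_rule_id"],
                         evidence=frozenset(d["evidence"])))
    return out
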