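"""Ontology-shaped domain model and the versioned knowledge base.

The model mirrors the fragment of ICNP + SSN/SOSA + FOAF that a remote
vital-sign monitoring system actually touches: patients (ICNP patient merged
with a FOAF person profile), sensor platforms linked to their owner
(``hasPlatform``), a catalog of vital-sign definitions (ICNP vital sign),
timestamped observations carrying a result value (SOSA observation + ICNP
result), named abnormal-range axioms per sign (the ``PerfAN``-style numeric
class restrictions), conjunctive rules, and an append-only alert log.

Only the classes and properties used by the monitoring loop are modelled;
this is deliberately not a general OWL store.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

from .errors import (ConfigError, DuplicateError, NominalValueError,
                     UnknownReferenceError)
from .intervals import Interval, normalize_region, region_contains, region_union

__all__ = [
    "Patient", "SensorPlatform", "VitalSignDefinition", "Observation",
    "AbnormalRangeAxiom", "KnowledgeBase", "axiom_class_name",
]

Value = Union[float, str]

_PLATFORM_KINDS = frozenset({"body", "ambient", "smart_device"})
_PROVENANCES = frozenset({"seed", "learned", "manual"})


def _require_aware(ts: _dt.datetime, what: str) -> _dt.datetime:
    if ts.tzinfo is None or ts.tzinfo.utcoffset(ts) is None:
        raise ConfigError(f"{what} must be timezone-aware (got naive {ts!r})")
    return ts


def axiom_class_name(sign_code: str) -> str:
    """Deterministic abnormal-range class name for a sign, e.g. Perf -> PerfAN."""
    return f"{sign_code}AN"


@dataclass
class Patient:
    patient_id: str
    name: Optional[str] = None
    birth_date: Optional[_dt.date] = None
    height_cm: Optional[float] = None
    weight_kg: Optional[float] = None
    platform_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ConfigError("patient_id must be non-empty")
        if self.height_cm is not None and not self.height_cm > 0:
            raise ConfigError("height must be strictly positive")
        if self.weight_kg is not None and not self.weight_kg > 0:
            raise ConfigError("weight must be strictly positive")


@dataclass
class SensorPlatform:
    platform_id: str
    owner: str
    kind: str
    sensor_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.kind not in _PLATFORM_KINDS:
            raise ConfigError(f"platform kind must be one of {sorted(_PLATFORM_KINDS)}")
        if not self.sensor_ids:
            raise ConfigError("a platform must host at least one sensor")


@dataclass
class VitalSignDefinition:
    """One entry of the vital-sign catalog (e.g. Perf, SpO2, NBP_Sys)."""

    code: str
    unit: str = ""
    value_kind: str = "real"
    default_plausible_range: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.value_kind not in ("real", "nominal"):
            raise ConfigError("value_kind must be 'real' or 'nominal'")
        if self.default_plausible_range is not None:
            lo, hi = self.default_plausible_range
            if not lo <= hi:
                raise ConfigError("plausible range must satisfy lo <= hi")


@dataclass
class Observation:
    """One timestamped measurement of one vital sign for one patient."""

    observation_id: str
    patient_id: str
    sign_code: str
    timestamp: _dt.datetime
    value: Value
    sensor_id: Optional[str] = None

    def __post_init__(self) -> None:
        _require_aware(self.timestamp, "observation timestamp")


@dataclass
class AbnormalRangeAxiom:
    """A named numeric region of a sign's domain, e.g. PerfAN = real < 0.5.

    The class is equivalent to a numeric restriction on the sign's result
    value; membership of a value in ``region`` is what the generic
    abnormal-vital-sign rule tests.
    """

    class_name: str
    sign_code: str
    region: tuple[Interval, ...]
    provenance: str = "manual"
    version: int = 1
    created_at: Optional[_dt.datetime] = None

    def __post_init__(self) -> None:
        if self.provenance not in _PROVENANCES:
            raise ConfigError(f"axiom provenance must be one of {sorted(_PROVENANCES)}")
        if self.version < 1:
            raise ConfigError("axiom version must be a positive integer")
        region = normalize_region(self.region)
        if region != tuple(self.region):
            raise ConfigError(
                f"axiom region for {self.class_name} is not normalized "
                "(use intervals.normalize_region)")
        self.region = region
        if self.created_at is not None:
            _require_aware(self.created_at, "axiom created_at")

    def contains(self, value: float) -> bool:
        return region_contains(self.region, value)


@dataclass
class Alert:
    alert_id: str
    patient_id: str
    timestamp: _dt.datetime
    label: str
    fired_rule_id: str
    evidence: frozenset[str]

    def __post_init__(self) -> None:
        _require_aware(self.timestamp, "alert timestamp")
        if not self.evidence:
            raise ConfigError("alert evidence must be non-empty")


class KnowledgeBase:
    """Versioned store of patients, platforms, signs, axioms, rules and alerts.

    Every mutating operation strictly increases ``version`` and appends a
    line to ``change_log``.  The alert log is append-only.  Derived class
    assertions (facts produced by forward chaining, e.g. ``AbnormalVitalSign``
    on a vital-sign individual) live in ``derived``.
    """

    def __init__(self) -> None:
        self.patients: dict[str, Patient] = {}
        self.platforms: dict[str, SensorPlatform] = {}
        self.sign_catalog: dict[str, VitalSignDefinition] = {}
        self.axioms: dict[str, AbnormalRangeAxiom] = {}
        self.rules: dict[str, "object"] = {}  # rule_id -> ConjunctiveRule
        self.alert_log: list[Alert] = []
        self.derived: dict[str, set[str]] = {}  # class_name -> individual ids
        self.version: int = 0
        self.change_log: list[str] = []
        self._observations: dict[str, Observation] = {}
        self._obs_by_patient_sign: dict[tuple[str, str], list[Observation]] = {}
        self._alert_counter: int = 0

    # -- bookkeeping ------------------------------------------------------

    def _bump(self, message: str) -> None:
        self.version += 1
        self.change_log.append(f"v{self.version}: {message}")

    # -- catalog and roster ----------------------------------------------

    def add_sign(self, sign: VitalSignDefinition) -> "KnowledgeBase":
        if sign.code in self.sign_catalog:
            raise DuplicateError(f"sign code {sign.code!r} already in catalog")
        self.sign_catalog[sign.code] = sign
        self._bump(f"add sign {sign.code}")
        return self

    def add_patient(self, patient: Patient) -> "KnowledgeBase":
        if patient.patient_id in self.patients:
            raise DuplicateError(f"patient {patient.patient_id!r} already exists")
        self.patients[patient.patient_id] = patient
        self._bump(f"add patient {patient.patient_id}")
        return self

    def add_platform(self, platform: SensorPlatform) -> "KnowledgeBase":
        if platform.owner not in self.patients:
            raise UnknownReferenceError(
                f"platform owner {platform.owner!r} is not a known patient")
        if platform.platform_id in self.platforms:
            raise DuplicateError(f"platform {platform.platform_id!r} already exists")
        self.platforms[platform.platform_id] = platform
        self.patients[platform.owner].platform_ids.add(platform.platform_id)
        self._bump(f"add platform {platform.platform_id}")
        return self

    # -- observations -----------------------------------------------------

    def assert_observation(self, obs: Observation) -> "KnowledgeBase":
        """Ingest one observation; rejects unknown references and duplicates."""
        if obs.patient_id not in self.patients:
            raise UnknownReferenceError(
                f"observation {obs.observation_id!r} refers to unknown patient "
                f"{obs.patient_id!r}")
        sign = self.sign_catalog.get(obs.sign_code)
        if sign is None:
            raise UnknownReferenceError(
                f"observation {obs.observation_id!r} refers to unknown sign "
                f"{obs.sign_code!r}")
        if obs.observation_id in self._observations:
            raise DuplicateError(
                f"duplicate observation id {obs.observation_id!r}")
        if sign.value_kind == "real":
            if isinstance(obs.value, bool) or not isinstance(obs.value, (int, float)):
                raise ConfigError(
                    f"sign {obs.sign_code!r} is real-valued but observation "
                    f"{obs.observation_id!r} carries {obs.value!r}")
            if math.isnan(float(obs.value)):
                raise ConfigError("observation value must not be NaN")
            obs.value = float(obs.value)
        else:
            if not isinstance(obs.value, str):
                raise ConfigError(
                    f"sign {obs.sign_code!r} is nominal but observation "
                    f"{obs.observation_id!r} carries {obs.value!r}")
        self._observations[obs.observation_id] = obs
        self._obs_by_patient_sign.setdefault(
            (obs.patient_id, obs.sign_code), []).append(obs)
        self._bump(f"assert observation {obs.observation_id}")
        return self

    def get_observation(self, observation_id: str) -> Observation:
        try:
            return self._observations[observation_id]
        except KeyError:
            raise UnknownReferenceError(
                f"no observation with id {observation_id!r}") from None

    def observations(self,
                     patient_id: Optional[str] = None,
                     sign_code: Optional[str] = None,
                     start: Optional[_dt.datetime] = None,
                     end: Optional[_dt.datetime] = None) -> list[Observation]:
        """Observations filtered by patient, sign and closed time window."""
        if patient_id is not None and sign_code is not None:
            pool: Iterable[Observation] = self._obs_by_patient_sign.get(
                (patient_id, sign_code), [])
        else:
            pool = self._observations.values()
            if patient_id is not None:
                pool = (o for o in pool if o.patient_id == patient_id)
            if sign_code is not None:
                pool = (o for o in pool if o.sign_code == sign_code)
        out = [o for o in pool
               if (start is None or o.timestamp >= start)
               and (end is None or o.timestamp <= end)]
        out.sort(key=lambda o: (o.timestamp, o.observation_id))
        return out

    def latest_observation(self, patient_id: str, sign_code: str,
                           at: Optional[_dt.datetime] = None,
                           window: Optional[float] = None) -> Optional[Observation]:
        """Most recent observation of a sign for a patient.

        With ``at`` set, only observations at or before ``at`` count; with
        ``window`` (seconds) set, the winner must additionally lie within
        ``window`` of ``at``.  Ties on timestamp break on observation id.
        """
        pool = self._obs_by_patient_sign.get((patient_id, sign_code))
        if not pool:
            return None
        if at is None:
            best = max(pool, key=lambda o: (o.timestamp, o.observation_id))
        else:
            eligible = [o for o in pool if o.timestamp <= at]
            if not eligible:
                return None
            best = max(eligible, key=lambda o: (o.timestamp, o.observation_id))
            if window is not None and (at - best.timestamp).total_seconds() > window:
                return None
        return best

    @property
    def observation_count(self) -> int:
        return len(self._observations)

    # -- abnormal-range axioms -------------------------------------------

    def upsert_abnormal_range(self, ax: AbnormalRangeAxiom) -> "KnowledgeBase":
        """Define an axiom, or widen the stored one by region union.

        Updating never forgets: the stored region becomes the union of the
        old and new regions, so repeated learning can only grow what counts
        as abnormal, and the result is independent of upsert order.
        """
        if ax.sign_code not in self.sign_catalog:
            raise UnknownReferenceError(
                f"axiom {ax.class_name!r} refers to unknown sign {ax.sign_code!r}")
        existing = self.axioms.get(ax.class_name)
        if existing is None:
            self.axioms[ax.class_name] = ax
            self._bump(f"define axiom {ax.class_name} region "
                       + "+".join(map(str, ax.region)))
        else:
            if existing.sign_code != ax.sign_code:
                raise ConfigError(
                    f"axiom {ax.class_name!r} already bound to sign "
                    f"{existing.sign_code!r}")
            merged = region_union(existing.region, ax.region)
            self.axioms[ax.class_name] = AbnormalRangeAxiom(
                class_name=ax.class_name,
                sign_code=ax.sign_code,
                region=merged,
                provenance=ax.provenance,
                version=existing.version + 1,
                created_at=ax.created_at or existing.created_at,
            )
            self._bump(f"update axiom {ax.class_name} region "
                       + "+".join(map(str, merged)))
        return self

    def axioms_for_sign(self, sign_code: str) -> list[AbnormalRangeAxiom]:
        return sorted((a for a in self.axioms.values() if a.sign_code == sign_code),
                      key=lambda a: a.class_name)

    def classify_result(self, sign_code: str, value: float) -> bool:
        """True iff ``value`` falls in any abnormal region declared for the sign."""
        sign = self.sign_catalog.get(sign_code)
        if sign is None:
            raise UnknownReferenceError(f"unknown sign {sign_code!r}")
        if sign.value_kind != "real":
            raise NominalValueError(
                f"sign {sign_code!r} is nominal; numeric range classification "
                "is undefined")
        return any(a.contains(float(value)) for a in self.axioms.values()
                   if a.sign_code == sign_code)

    # -- rules, alerts, derived facts ------------------------------------

    def add_rule(self, rule) -> "KnowledgeBase":
        rule.validate()
        self.rules[rule.rule_id] = rule
        self._bump(f"install rule {rule.rule_id}")
        return self

    def next_alert_id(self) -> str:
        self._alert_counter += 1
        return f"alert-{self._alert_counter:06d}"

    def append_alert(self, alert: Alert) -> "KnowledgeBase":
        if alert.fired_rule_id not in self.rules:
            raise UnknownReferenceError(
                f"alert {alert.alert_id!r} fired by unknown rule "
                f"{alert.fired_rule_id!r}")
        for oid in alert.evidence:
            if oid not in self._observations:
                raise UnknownReferenceError(
                    f"alert {alert.alert_id!r} cites unknown observation {oid!r}")
        self.alert_log.append(alert)
        self._bump(f"alert {alert.alert_id} [{alert.label}] "
                   f"patient {alert.patient_id}")
        return self

    def assert_derived(self, class_name: str, individual: str) -> bool:
        """Record a derived class assertion; returns True if it is new."""
        members = self.derived.setdefault(class_name, set())
        if individual in members:
            return False
        members.add(individual)
        self._bump(f"derive {class_name}({individual})")
        return True

    def latest_event_time(self) -> Optional[_dt.datetime]:
        """Most recent observation or alert timestamp, if any."""
        times = [o.timestamp for o in self._observations.values()]
        times += [a.timestamp for a in self.alert_log]
        return max(times) if times else None

    # -- structural equality ----------------------------------------------

    def structurally_equal(self, other: "KnowledgeBase") -> bool:
        """Equality of content, ignoring version counters and ordering."""
        def axiom_key(a: AbnormalRangeAxiom):
            return (a.class_name, a.sign_code, a.region, a.provenance,
                    a.created_at)

        def alert_key(a: Alert):
            return (a.alert_id, a.patient_id, a.timestamp, a.label,
                    a.fired_rule_id, a.evidence)

        if self.patients != other.patients:
            return False
        if self.platforms != other.platforms:
            return False
        if self.sign_catalog != other.sign_catalog:
            return False
        if set(self.axioms) != set(other.axioms):
            return False
        for name in self.axioms:
            if axiom_key(self.axioms[name]) != axiom_key(other.axioms[name]):
                return False
        if set(self.rules) != set(other.rules):
            return False
        for rid in self.rules:
            if self.rules[rid].to_dict() != other.rules[rid].to_dict():
                return False
        if sorted(map(alert_key, self.alert_log)) != sorted(map(alert_key, other.alert_log)):
            return False
        if self._observations != other._observations:
            return False
        if {k: v for k, v in self.derived.items() if v} != \
                {k: v for k, v in other.derived.items() if v}:
            return False
        return True
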