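"""Persistence: Turtle export/import of the knowledge base, JSON for axioms
and rules, CSV observation ingestion, JSONL alert streams.

Turtle dialect
--------------
One artifact-owned namespace (``vw:``) carries all predicates; the borrowed
class names (``icnp:Patient``, ``sosa:Observation``, ``icnp:Result``,
``icnp:VitalSign``, ``ssn:Platform``, ``foaf:Person``) are name-compatible
references typed onto the individuals — the upstream vocabularies are not
imported.  Numeric values are serialized as ``repr`` string literals so
floats round-trip bit-exactly (plain ``xsd:double`` literals are rounded by
common serializers).  Rules are embedded as their canonical JSON text in a
single literal.  Timestamps are ISO-8601 with timezone.

CSV observation schema
----------------------
``patient_id,sensor_id,sign_code,timestamp,value`` — timestamps ISO-8601
(naive timestamps are rejected), values numeric for real-valued signs.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from typing import IO, Iterable, Optional

import pandas as pd
from rdflib import BNode, Graph, Literal, Namespace, RDF, URIRef

from .engine import ConjunctiveRule
from .errors import DataError
from .intervals import Interval
from .model import (AbnormalRangeAxiom, Alert, KnowledgeBase, Observation,
                    Patient, SensorPlatform, VitalSignDefinition)

__all__ = [
    "export_turtle", "import_turtle",
    "axioms_to_json", "axioms_from_json", "rules_to_json", "rules_from_json",
    "read_observations_csv", "write_observations_csv",
]

VW = Namespace("https://vitalwatch.example/ns#")
ICNP = Namespace("https://vitalwatch.example/icnp#")
SOSA = Namespace("http://www.w3.org/ns/sosa/")
SSN = Namespace("http://www.w3.org/ns/ssn/")
FOAF = Namespace("http://xmlns.com/foaf/0.1/")

OBS_CSV_COLUMNS = ["patient_id", "sensor_id", "sign_code", "timestamp", "value"]


def _num(x: float) -> Literal:
    return Literal(repr(float(x)))


def _parse_num(lit) -> float:
    return float(str(lit))


# ---------------------------------------------------------------------------
# Turtle export
# ---------------------------------------------------------------------------

def export_turtle(kb: KnowledgeBase) -> str:
    """Serialize the whole knowledge base to Turtle text."""
    g = Graph()
    for prefix, ns in (("vw", VW), ("icnp", ICNP), ("sosa", SOSA),
                       ("ssn", SSN), ("foaf", FOAF)):
        g.bind(prefix, ns)
    g.add((VW.kb, RDF.type, VW.KnowledgeBase))

    for sign in kb.sign_catalog.values():
        n = VW[f"sign/{sign.code}"]
        g.add((n, RDF.type, ICNP.VitalSign))
        g.add((n, VW.code, Literal(sign.code)))
        if sign.unit:
            g.add((n, VW.unit, Literal(sign.unit)))
        g.add((n, VW.valueKind, Literal(sign.value_kind)))
        if sign.default_plausible_range is not None:
            lo, hi = sign.default_plausible_range
            g.add((n, VW.plausibleLower, _num(lo)))
            g.add((n, VW.plausibleUpper, _num(hi)))

    for p in kb.patients.values():
        n = VW[f"patient/{p.patient_id}"]
        g.add((n, RDF.type, ICNP.Patient))
        g.add((n, RDF.type, FOAF.Person))
        g.add((n, VW.patientId, Literal(p.patient_id)))
        if p.name is not None:
            g.add((n, FOAF.name, Literal(p.name)))
        if p.birth_date is not None:
            g.add((n, VW.birthDate, Literal(p.birth_date.isoformat())))
        if p.height_cm is not None:
            g.add((n, VW.heightCm, _num(p.height_cm)))
        if p.weight_kg is not None:
            g.add((n, VW.weightKg, _num(p.weight_kg)))
        for plid in sorted(p.platform_ids):
            g.add((n, VW.hasPlatform, VW[f"platform/{plid}"]))

    for pl in kb.platforms.values():
        n = VW[f"platform/{pl.platform_id}"]
        g.add((n, RDF.type, SSN.Platform))
        g.add((n, VW.platformId, Literal(pl.platform_id)))
        g.add((n, VW.ownedBy, VW[f"patient/{pl.owner}"]))
        g.add((n, VW.platformKind, Literal(pl.kind)))
        for sid in sorted(pl.sensor_ids):
            g.add((n, VW.hostsSensor, Literal(sid)))

    for o in kb.observations():
        n = VW[f"obs/{o.observation_id}"]
        rn = VW[f"result/{o.observation_id}"]
        g.add((n, RDF.type, SOSA.Observation))
        g.add((n, VW.observationId, Literal(o.observation_id)))
        g.add((n, VW.forPatient, VW[f"patient/{o.patient_id}"]))
        g.add((n, VW.ofSign, VW[f"sign/{o.sign_code}"]))
        g.add((n, SOSA.resultTime, Literal(o.timestamp.isoformat())))
        g.add((n, SOSA.hasResult, rn))
        g.add((rn, RDF.type, ICNP.Result))
        if isinstance(o.value, float):
            g.add((rn, VW.numericValue, _num(o.value)))
        else:
            g.add((rn, VW.nominalValue, Literal(o.value)))
        if o.sensor_id is not None:
            g.add((n, VW.bySensor, Literal(o.sensor_id)))

    for ax in kb.axioms.values():
        n = VW[f"axiom/{ax.class_name}"]
        g.add((n, RDF.type, VW.AbnormalRangeAxiom))
        g.add((n, VW.className, Literal(ax.class_name)))
        g.add((n, VW.ofSign, VW[f"sign/{ax.sign_code}"]))
        g.add((n, VW.provenance, Literal(ax.provenance)))
        g.add((n, VW.axiomVersion, Literal(ax.version)))
        if ax.created_at is not None:
            g.add((n, VW.createdAt, Literal(ax.created_at.isoformat())))
        for iv in ax.region:
            b = BNode()
            g.add((n, VW.interval, b))
            g.add((b, VW["lower"], _num(iv.lower)))
            g.add((b, VW["upper"], _num(iv.upper)))
            g.add((b, VW.lowerClosed, Literal(iv.lower_closed)))
            g.add((b, VW.upperClosed, Literal(iv.upper_closed)))

    for rule in kb.rules.values():
        n = VW[f"rule/{rule.rule_id}"]
        g.add((n, RDF.type, VW.ConjunctiveRule))
        g.add((n, VW.ruleId, Literal(rule.rule_id)))
        g.add((n, VW.ruleJson, Literal(json.dumps(rule.to_dict(),
                                                  sort_keys=True))))

    for a in kb.alert_log:
        n = VW[f"alert/{a.alert_id}"]
        g.add((n, RDF.type, VW.Alert))
        g.add((n, VW.alertId, Literal(a.alert_id)))
        g.add((n, VW.forPatient, VW[f"patient/{a.patient_id}"]))
        g.add((n, VW.at, Literal(a.timestamp.isoformat())))
        g.add((n, VW.alertLabel, Literal(a.label)))
        g.add((n, VW.firedRule, VW[f"rule/{a.fired_rule_id}"]))
        for oid in sorted(a.evidence):
            g.add((n, VW.evidence, VW[f"obs/{oid}"]))

    for class_name, members in sorted(kb.derived.items()):
        for ind in sorted(members):
            g.add((VW[f"individual/{ind}"], VW.hasDerivedClass,
                   Literal(class_name)))

    return g.serialize(format="turtle")


# ---------------------------------------------------------------------------
# Turtle import
# ---------------------------------------------------------------------------

def _one(g: Graph, s, p, what: str):
    vals = list(g.objects(s, p))
    if len(vals) != 1:
        raise DataError(f"expected exactly one {what} on {s}, got {len(vals)}")
    return vals[0]


def _opt(g: Graph, s, p):
    vals = list(g.objects(s, p))
    return vals[0] if vals else None


def _local(node: URIRef, kind: str) -> str:
    prefix = str(VW) + kind + "/"
    text = str(node)
    if not text.startswith(prefix):
        raise DataError(f"node {text} is not a vw {kind} reference")
    return text[len(prefix):]


def import_turtle(text: str) -> KnowledgeBase:
    """Rebuild a knowledge base from its Turtle export.

    The result equals the exported KB up to version counters and ordering.
    Unknown predicates in the artifact namespace are rejected.
    """
    g = Graph()
    try:
        g.parse(data=text, format="turtle")
    except Exception as exc:  # rdflib raises several parser error types
        raise DataError(f"malformed Turtle document: {exc}") from exc

    known = {VW[t] for t in (
        "kb", "KnowledgeBase", "code", "unit", "valueKind", "plausibleLower",
        "plausibleUpper", "patientId", "birthDate", "heightCm", "weightKg",
        "hasPlatform", "platformId", "ownedBy", "platformKind", "hostsSensor",
        "observationId", "forPatient", "ofSign", "bySensor", "numericValue",
        "nominalValue", "className", "provenance", "axiomVersion",
        "createdAt", "interval", "lower", "upper", "lowerClosed",
        "upperClosed", "ruleId", "ruleJson", "alertId", "at", "alertLabel",
        "firedRule", "evidence", "hasDerivedClass", "AbnormalRangeAxiom",
        "ConjunctiveRule", "Alert")}
    for _s, p, _o in g:
        if str(p).startswith(str(VW)) and p not in known:
            raise DataError(f"unknown predicate {p} in knowledge-base document")

    kb = KnowledgeBase()

    for n in sorted(g.subjects(RDF.type, ICNP.VitalSign)):
        rng = None
        lo, hi = _opt(g, n, VW.plausibleLower), _opt(g, n, VW.plausibleUpper)
        if lo is not None and hi is not None:
            rng = (_parse_num(lo), _parse_num(hi))
        unit = _opt(g, n, VW.unit)
        kb.add_sign(VitalSignDefinition(
            code=str(_one(g, n, VW.code, "sign code")),
            unit=str(unit) if unit is not None else "",
            value_kind=str(_one(g, n, VW.valueKind, "value kind")),
            default_plausible_range=rng))

    for n in sorted(g.subjects(RDF.type, ICNP.Patient)):
        bd = _opt(g, n, VW.birthDate)
        h, w = _opt(g, n, VW.heightCm), _opt(g, n, VW.weightKg)
        name = _opt(g, n, FOAF.name)
        kb.add_patient(Patient(
            patient_id=str(_one(g, n, VW.patientId, "patient id")),
            name=str(name) if name is not None else None,
            birth_date=_dt.date.fromisoformat(str(bd)) if bd is not None else None,
            height_cm=_parse_num(h) if h is not None else None,
            weight_kg=_parse_num(w) if w is not None else None))

    for n in sorted(g.subjects(RDF.type, SSN.Platform)):
        kb.add_platform(SensorPlatform(
            platform_id=str(_one(g, n, VW.platformId, "platform id")),
            owner=_local(_one(g, n, VW.ownedBy, "platform owner"), "patient"),
            kind=str(_one(g, n, VW.platformKind, "platform kind")),
            sensor_ids={str(s) for s in g.objects(n, VW.hostsSensor)}))

    for n in sorted(g.subjects(RDF.type, SOSA.Observation)):
        rn = _one(g, n, SOSA.hasResult, "observation result")
        num = _opt(g, rn, VW.numericValue)
        if num is not None:
            value: object = _parse_num(num)
        else:
            value = str(_one(g, rn, VW.nominalValue, "result value"))
        sensor = _opt(g, n, VW.bySensor)
        kb.assert_observation(Observation(
            observation_id=str(_one(g, n, VW.observationId, "observation id")),
            patient_id=_local(_one(g, n, VW.forPatient, "patient ref"), "patient"),
            sign_code=_local(_one(g, n, VW.ofSign, "sign ref"), "sign"),
            timestamp=_dt.datetime.fromisoformat(
                str(_one(g, n, SOSA.resultTime, "result time"))),
            value=value,
            sensor_id=str(sensor) if sensor is not None else None))

    for n in sorted(g.subjects(RDF.type, VW.AbnormalRangeAxiom)):
        region = []
        for b in g.objects(n, VW.interval):
            region.append(Interval(
                lower=_parse_num(_one(g, b, VW["lower"], "interval lower")),
                upper=_parse_num(_one(g, b, VW["upper"], "interval upper")),
                lower_closed=bool(_one(g, b, VW.lowerClosed, "tag").toPython()),
                upper_closed=bool(_one(g, b, VW.upperClosed, "tag").toPython())))
        created = _opt(g, n, VW.createdAt)
        sign_code = _local(_one(g, n, VW.ofSign, "sign ref"), "sign")
        if sign_code not in kb.sign_catalog:
            raise DataError(f"axiom references unknown sign {sign_code!r}")
        ax = AbnormalRangeAxiom(
            class_name=str(_one(g, n, VW.className, "class name")),
            sign_code=sign_code,
            region=tuple(sorted(region, key=lambda iv: iv.lower)),
            provenance=str(_one(g, n, VW.provenance, "provenance")),
            version=int(_one(g, n, VW.axiomVersion, "version").toPython()),
            created_at=(_dt.datetime.fromisoformat(str(created))
                        if created is not None else None))
        kb.axioms[ax.class_name] = ax
        kb._bump(f"import axiom {ax.class_name}")

    for n in sorted(g.subjects(RDF.type, VW.ConjunctiveRule)):
        rule = ConjunctiveRule.from_dict(
            json.loads(str(_one(g, n, VW.ruleJson, "rule JSON"))))
        kb.add_rule(rule)

    max_alert = 0
    for n in sorted(g.subjects(RDF.type, VW.Alert)):
        aid = str(_one(g, n, VW.alertId, "alert id"))
        kb.append_alert(Alert(
            alert_id=aid,
            patient_id=_local(_one(g, n, VW.forPatient, "patient ref"), "patient"),
            timestamp=_dt.datetime.fromisoformat(str(_one(g, n, VW.at, "time"))),
            label=str(_one(g, n, VW.alertLabel, "label")),
            fired_rule_id=_local(_one(g, n, VW.firedRule, "rule ref"), "rule"),
            evidence=frozenset(_local(o, "obs")
                               for o in g.objects(n, VW.evidence))))
        if aid.startswith("alert-"):
            try:
                max_alert = max(max_alert, int(aid.split("-")[-1]))
            except ValueError:
                pass
    kb._alert_counter = max_alert

    for n, class_lit in sorted(g.subject_objects(VW.hasDerivedClass)):
        kb.assert_derived(str(class_lit), _local(n, "individual"))

    return kb


# ---------------------------------------------------------------------------
# JSON for axioms and rules
# ---------------------------------------------------------------------------

def _interval_to_json(iv: Interval) -> dict:
    def bound(x: float) -> object:
        return repr(x) if math.isinf(x) else x
    return {"lower": bound(iv.lower), "upper": bound(iv.upper),
            "lower_closed": iv.lower_closed, "upper_closed": iv.upper_closed}


def _interval_from_json(d: dict) -> Interval:
    return Interval(float(d["lower"]), float(d["upper"]),
                    bool(d["lower_closed"]), bool(d["upper_closed"]))


def axiom_to_dict(ax: AbnormalRangeAxiom) -> dict:
    return {"class_name": ax.class_name, "sign_code": ax.sign_code,
            "region": [_interval_to_json(iv) for iv in ax.region],
            "provenance": ax.provenance, "version": ax.version,
            "created_at": ax.created_at.isoformat() if ax.created_at else None}


def axiom_from_dict(d: dict) -> AbnormalRangeAxiom:
    return AbnormalRangeAxiom(
        class_name=d["class_name"], sign_code=d["sign_code"],
        region=tuple(_interval_from_json(iv) for iv in d["region"]),
        provenance=d.get("provenance", "manual"),
        version=int(d.get("version", 1)),
        created_at=(_dt.datetime.fromisoformat(d["created_at"])
                    if d.get("created_at") else None))


def axioms_to_json(axioms: Iterable[AbnormalRangeAxiom]) -> str:
    return json.dumps([axiom_to_dict(a) for a in
                       sorted(axioms, key=lambda a: a.class_name)],
                      indent=2, sort_keys=True)


def axioms_from_json(text: str) -> list[AbnormalRangeAxiom]:
    return [axiom_from_dict(d) for d in json.loads(text)]


def rules_to_json(rules: Iterable[ConjunctiveRule]) -> str:
    return json.dumps([r.to_dict() for r in
                       sorted(rules, key=lambda r: r.rule_id)],
                      indent=2, sort_keys=True)


def rules_from_json(text: str) -> list[ConjunctiveRule]:
    return [ConjunctiveRule.from_dict(d) for d in json.loads(text)]


# ---------------------------------------------------------------------------
# observation CSV
# ---------------------------------------------------------------------------

def read_observations_csv(fp: IO[str] | str) -> list[Observation]:
    """Read observations from the ingestion CSV schema.

    Row ``i`` without an explicit observation id gets a deterministic id
    ``<patient>-<sign>-r<i>``.
    """
    df = pd.read_csv(fp, dtype=str)
    missing = [c for c in OBS_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"observation CSV lacks columns {missing}; header "
                        f"must be {','.join(OBS_CSV_COLUMNS)}")
    out: list[Observation] = []
    for i, row in enumerate(df.itertuples(index=False)):
        ts = _dt.datetime.fromisoformat(str(row.timestamp))
        if ts.tzinfo is None:
            raise DataError(
                f"row {i}: timestamp {row.timestamp!r} has no timezone")
        raw = str(row.value)
        try:
            value: object = float(raw)
        except ValueError:
            value = raw
        oid = getattr(row, "observation_id", None) or \
            f"{row.patient_id}-{row.sign_code}-r{i:06d}"
        sensor = row.sensor_id if isinstance(row.sensor_id, str) and \
            row.sensor_id else None
        out.append(Observation(observation_id=str(oid),
                               patient_id=str(row.patient_id),
                               sign_code=str(row.sign_code),
                               timestamp=ts, value=value, sensor_id=sensor))
    return out


def write_observations_csv(observations: Iterable[Observation],
                           fp: IO[str] | str) -> None:
    rows = [{"patient_id": o.patient_id, "sensor_id": o.sensor_id or "",
             "sign_code": o.sign_code, "timestamp": o.timestamp.isoformat(),
             "value": repr(o.value) if isinstance(o.value, float) else o.value,
             "observation_id": o.observation_id}
            for o in observations]
    pd.DataFrame(rows, columns=OBS_CSV_COLUMNS + ["observation_id"]).to_csv(
        fp, index=False)
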