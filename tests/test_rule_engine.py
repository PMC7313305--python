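import datetime as dt
import io
import random

import numpy as np
import pytest

from vitalwatch import (AbnormalRangeAxiom, Observation, abnormal_alert_rule,
                        apply_all, emergency_rule_from_conditions, gm_rule,
                        match_rule, monitor_stream, normalize_region,
                        parse_condition_text)
from vitalwatch.engine import (AssertClass, ClassAtom, ComparisonAtom,
                               ConjunctiveRule, EmitAlert, PropertyAtom,
                               RangeAtom, alerts_from_jsonl, alerts_to_jsonl,
                               rule_from_json, rule_from_swrl, rule_to_json,
                               rule_to_swrl)
from vitalwatch.errors import ConfigError
from vitalwatch.intervals import half_line

from conftest import at, make_kb, perf_axiom
from oracles import enumerate_bindings


# -- the generic rule -------------------------------------------------------

def test_generic_rule_has_six_atoms_and_asserts_abnormal_vital_sign():
    g = gm_rule()
    assert len(g.antecedent) == 6
    assert g.consequent == AssertClass("AbnormalVitalSign", "?v")
    g.validate()  # safety: consequent variable bound in the antecedent


def test_unsafe_rule_is_rejected():
    with pytest.raises(ConfigError):
        ConjunctiveRule("bad", (ClassAtom("Patient", "?p"),),
                        AssertClass("X", "?q")).validate()


# -- matching ---------------------------------------------------------------

def test_match_on_empty_kb_is_empty(kb):
    assert match_rule(kb, gm_rule()) == []


def test_single_abnormal_observation_yields_exactly_one_binding(kb):
    kb.upsert_abnormal_range(AbnormalRangeAxiom(
        "TempAN", "Temp", normalize_region([half_line(">", 38.5)])))
    kb.assert_observation(Observation("o1", "P1", "Temp", at(0), 39.5))
    bindings = match_rule(kb, gm_rule())
    assert bindings == [{"?v": "vsign:P1:Temp", "?o": "obs:o1",
                         "?r": "result:o1"}]


def test_normal_observation_yields_no_binding(kb):
    kb.upsert_abnormal_range(AbnormalRangeAxiom(
        "TempAN", "Temp", normalize_region([half_line(">", 38.5)])))
    kb.assert_observation(Observation("o1", "P1", "Temp", at(0), 37.0))
    assert match_rule(kb, gm_rule()) == []


def _random_small_kb(rng):
    kb = make_kb(("P1", "P2"))
    signs = ["Perf", "Temp", "NBP_Sys"]
    for sign in signs:
        if rng.random() < 0.7:
            op = rng.choice(["<", ">"])
            c = {"Perf": rng.uniform(0.2, 2.0),
                 "Temp": rng.uniform(35, 40),
                 "NBP_Sys": rng.uniform(90, 140)}[sign]
            kb.upsert_abnormal_range(AbnormalRangeAxiom(
                f"{sign}AN", sign, normalize_region([half_line(op, c)])))
    n_obs = rng.randrange(0, 9)
    for i in range(n_obs):
        sign = rng.choice(signs)
        value = {"Perf": rng.uniform(0.0, 2.5),
                 "Temp": rng.uniform(34, 41),
                 "NBP_Sys": rng.uniform(80, 150)}[sign]
        kb.assert_observation(Observation(
            f"o{i}", rng.choice(["P1", "P2"]), sign,
            at(rng.randrange(0, 300)), value))
    return kb


def _random_rule(rng):
    kind = rng.randrange(3)
    if kind == 0:
        return gm_rule()
    if kind == 1:
        n = rng.randrange(1, 3)
        conds = []
        for _ in range(n):
            sign = rng.choice(["Perf", "Temp", "NBP_Sys"])
            c = {"Perf": rng.uniform(0.2, 2.0), "Temp": rng.uniform(35, 40),
                 "NBP_Sys": rng.uniform(90, 140)}[sign]
            conds.append((sign, rng.choice(["<", "<=", ">", ">="]), c))
        return emergency_rule_from_conditions("X", conds,
                                              co_window=rng.choice([60, 1e9]))
    # an assorted conjunction over observation structure
    return ConjunctiveRule(
        "assorted",
        (ClassAtom("Observation", "?o"), PropertyAtom("hasResult", "?o", "?r"),
         PropertyAtom("hasPatient", "?o", "?p"),
         ComparisonAtom("?r", rng.choice(["<", ">="]),
                        rng.uniform(0, 120))),
        AssertClass("Flagged", "?o"))


def test_matching_equals_exhaustive_enumeration_on_random_kbs():
    """Joint check of the matcher against brute-force assignment search."""
    rng = random.Random(2026)
    for _ in range(30):
        kb = _random_small_kb(rng)
        rule = _random_rule(rng)
        got = {frozenset(b.items()) for b in match_rule(kb, rule)}
        assert got == enumerate_bindings(kb, rule)


# -- forward chaining -------------------------------------------------------

def test_apply_all_without_rules_changes_nothing(kb):
    kb.assert_observation(Observation("o1", "P1", "Temp", at(0), 37.0))
    v = kb.version
    _kb, alerts = apply_all(kb, [])
    assert alerts == []
    assert kb.version == v
    assert kb.derived == {}


def test_generic_rule_derives_single_class_assertion(kb):
    kb.upsert_abnormal_range(perf_axiom(0.5))
    kb.assert_observation(Observation("o1", "P1", "Perf", at(0), 0.2))
    _kb, alerts = apply_all(kb, [gm_rule()])
    assert kb.derived["AbnormalVitalSign"] == {"vsign:P1:Perf"}
    assert alerts == []


def test_chained_rules_fire_alert_from_derived_class(kb):
    kb.upsert_abnormal_range(perf_axiom(0.5))
    kb.assert_observation(Observation("o1", "P1", "Perf", at(0), 0.2))
    _kb, alerts = apply_all(kb, [gm_rule(), abnormal_alert_rule()])
    assert len(alerts) == 1
    assert alerts[0].evidence == frozenset({"o1"})
    assert alerts[0].patient_id == "P1"


def test_fixpoint_is_order_independent(kb_two_patients):
    kb_template = kb_two_patients
    kb_template.upsert_abnormal_range(perf_axiom(0.5))
    rules = [gm_rule(), abnormal_alert_rule(),
             emergency_rule_from_conditions("LOW", [("Perf", "<", 0.5)])]
    results = []
    for order in ([0, 1, 2], [2, 1, 0], [1, 2, 0]):
        kb = make_kb(("P1", "P2"))
        kb.upsert_abnormal_range(perf_axiom(0.5))
        for i, pid in enumerate(["P1", "P1", "P2"]):
            kb.assert_observation(Observation(
                f"o{i}", pid, "Perf", at(i), [0.2, 0.4, 0.9][i]))
        _kb, alerts = apply_all(kb, [rules[i] for i in order])
        results.append((dict(kb.derived),
                        sorted((a.patient_id, a.label, tuple(sorted(a.evidence)))
                               for a in alerts)))
    assert results[0] == results[1] == results[2]


def test_termination_on_randomized_kbs():
    rng = random.Random(5)
    for _ in range(10):
        kb = _random_small_kb(rng)
        apply_all(kb, [gm_rule(), abnormal_alert_rule()])  # must not hang
        # fixpoint: a second application derives nothing new
        derived = {k: set(v) for k, v in kb.derived.items()}
        apply_all(kb, [gm_rule()])
        assert {k: set(v) for k, v in kb.derived.items()} == derived


# -- emergency rules --------------------------------------------------------

def test_printed_rule_text_parses_to_four_conditions():
    conds = parse_condition_text(
        "Perf < 0.5 and AWV < 3749.05 and AWF < 10.4 and NBP (Sys) < 105")
    assert conds == [("Perf", "<", 0.5), ("AWV", "<", 3749.05),
                     ("AWF", "<", 10.4), ("NBP_Sys", "<", 105.0)]
    rule = emergency_rule_from_conditions("SpO2 LOW PERF", conds)
    comparisons = [a for a in rule.antecedent
                   if isinstance(a, ComparisonAtom)]
    assert len(comparisons) == 4
    assert rule.consequent == EmitAlert("SpO2 LOW PERF")


def test_single_condition_rule_fires_on_latest_observation_only(kb):
    rule = emergency_rule_from_conditions("HOT", [("Temp", ">", 40.0)],
                                          co_window=1e9)
    # older observation is above threshold, latest is not -> no firing
    kb.assert_observation(Observation("o1", "P1", "Temp", at(0), 41.0))
    kb.assert_observation(Observation("o2", "P1", "Temp", at(60), 39.0))
    assert match_rule(kb, rule) == []
    # a new, hotter latest observation fires
    kb.assert_observation(Observation("o3", "P1", "Temp", at(120), 40.5))
    bindings = match_rule(kb, rule)
    assert [b["?r_Temp"] for b in bindings] == ["result:o3"]


def test_duplicate_sign_conditions_bind_one_observation(kb):
    rule = emergency_rule_from_conditions(
        "BAND", [("Temp", ">", 40.0), ("Temp", "<", 45.0)], co_window=1e9)
    latest_atoms = [a for a in rule.antecedent
                    if isinstance(a, PropertyAtom)]
    assert len(latest_atoms) == 1  # one bound observation for both conditions
    kb.assert_observation(Observation("o1", "P1", "Temp", at(0), 42.0))
    assert len(match_rule(kb, rule)) == 1
    kb.assert_observation(Observation("o2", "P1", "Temp", at(60), 46.0))
    assert match_rule(kb, rule) == []


def test_empty_conditions_are_rejected():
    with pytest.raises(ConfigError):
        emergency_rule_from_conditions("X", [])


def test_co_occurrence_window_excludes_stale_observations(kb):
    rule = emergency_rule_from_conditions(
        "BOTH", [("Perf", "<", 0.5), ("Temp", ">", 40.0)], co_window=60.0)
    kb.assert_observation(Observation("o1", "P1", "Temp", at(0), 41.0))
    kb.assert_observation(Observation("o2", "P1", "Perf", at(300), 0.2))
    assert match_rule(kb, rule) == []  # Temp reading is 5 minutes stale


# -- alert soundness on synthetic data --------------------------------------

def test_every_alert_evidence_satisfies_the_planted_predicate():
    from vitalwatch import (PlantedEmergency, SignalModel, generate_stream,
                            observations_from_frame, bootstrap_kb)
    predicate = (("Perf", "<", 0.5), ("NBP_Sys", "<", 105.0))
    models = [SignalModel("Perf", 1.4, 0.25), SignalModel("NBP_Sys", 120, 8)]
    obs, ann = generate_stream(
        2, models, [PlantedEmergency("SpO2 LOW PERF", predicate,
                                     episode_rate_per_day=24)],
        duration_hours=8, seed=17)
    kb = bootstrap_kb(["P1", "P2"])
    rule = emergency_rule_from_conditions("SpO2 LOW PERF", list(predicate))
    kb.add_rule(rule)
    result = monitor_stream(kb, observations_from_frame(obs),
                            gm_alerts=False)
    assert len(result.alerts) == len(ann)
    ops = {"<": lambda v, c: v < c, ">": lambda v, c: v > c}
    for alert in result.alerts:
        values = {kb.get_observation(oid).sign_code: kb.get_observation(oid).value
                  for oid in alert.evidence}
        for sign, op, c in predicate:
            assert ops[op](values[sign], c)


# -- serialization ----------------------------------------------------------

@pytest.mark.parametrize("rule", [
    gm_rule(),
    abnormal_alert_rule(),
    emergency_rule_from_conditions(
        "SpO2 LOW PERF",
        [("Perf", "<", 0.5), ("AWV", "<", 3749.05),
         ("AWF", "<", 10.4), ("NBP_Sys", "<", 105.0)],
        provenance="learned"),
], ids=["gm", "generic-alert", "learned-alarm"])
def test_rule_json_and_swrl_text_round_trip(rule):
    assert rule_from_json(rule_to_json(rule)).to_dict() == rule.to_dict()
    text = rule_to_swrl(rule)
    back = rule_from_swrl(text, rule_id=rule.rule_id, label=rule.label,
                          provenance=rule.provenance,
                          co_window=rule.co_window)
    assert back.antecedent == rule.antecedent
    assert back.consequent == rule.consequent


def test_alert_jsonl_round_trip(kb):
    kb.upsert_abnormal_range(perf_axiom(0.5))
    kb.assert_observation(Observation("o1", "P1", "Perf", at(0), 0.2))
    _kb, alerts = apply_all(kb, [gm_rule(), abnormal_alert_rule()])
    buf = io.StringIO()
    alerts_to_jsonl(alerts, buf)
    buf.seek(0)
    back = alerts_from_jsonl(buf)
    assert [(a.alert_id, a.patient_id, a.timestamp, a.label, a.evidence)
            for a in back] == \
        [(a.alert_id, a.patient_id, a.timestamp, a.label, a.evidence)
         for a in alerts]
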