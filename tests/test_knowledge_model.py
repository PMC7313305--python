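import datetime as dt
import math

import numpy as np
import pytest

from vitalwatch import (AbnormalRangeAxiom, KnowledgeBase, Observation,
                        Patient, SensorPlatform, normalize_region)
from vitalwatch.errors import (ConfigError, DataError, DuplicateError,
                               NominalValueError, UnknownReferenceError)
from vitalwatch.intervals import Interval, half_line
from vitalwatch.serialize import (axioms_from_json, axioms_to_json,
                                  export_turtle, import_turtle)

from conftest import at, make_kb, perf_axiom
from oracles import classify_by_scan


# -- observations -----------------------------------------------------------

def test_observation_for_unknown_patient_is_rejected(kb):
    with pytest.raises(UnknownReferenceError):
        kb.assert_observation(Observation("o1", "nobody", "Temp", at(0), 37.0))


def test_observation_for_unknown_sign_is_rejected(kb):
    with pytest.raises(UnknownReferenceError):
        kb.assert_observation(Observation("o1", "P1", "XYZ", at(0), 1.0))


def test_duplicate_observation_id_is_rejected(kb):
    kb.assert_observation(Observation("o1", "P1", "Temp", at(0), 37.0))
    with pytest.raises(DuplicateError):
        kb.assert_observation(Observation("o1", "P1", "Temp", at(1), 37.5))


def test_single_observation_is_retrievable_every_way(kb):
    kb.assert_observation(Observation("o1", "P1", "Temp", at(0), 37.0))
    assert kb.observation_count == 1
    assert kb.get_observation("o1").value == 37.0
    assert [o.observation_id for o in kb.observations(patient_id="P1")] == ["o1"]
    assert [o.observation_id
            for o in kb.observations(sign_code="Temp",
                                     start=at(-1), end=at(1))] == ["o1"]


def test_naive_timestamps_are_rejected():
    with pytest.raises(ConfigError):
        Observation("o1", "P1", "Temp", dt.datetime(2026, 1, 1), 37.0)


def test_bulk_retrieval_matches_linear_scan_oracle(kb_two_patients):
    kb = kb_two_patients
    rng = np.random.default_rng(1234)
    signs = ["Temp", "Perf", "Pulse"]
    asserted = []
    for i in range(1000):
        obs = Observation(
            observation_id=f"o{i}",
            patient_id=f"P{1 + rng.integers(2)}",
            sign_code=signs[rng.integers(len(signs))],
            timestamp=at(float(rng.integers(0, 3600))),
            value=float(rng.normal(50, 10)))
        kb.assert_observation(obs)
        asserted.append(obs)
    for pid in ("P1", "P2"):
        for sign in signs:
            expected = sorted(o.observation_id for o in asserted
                              if o.patient_id == pid and o.sign_code == sign)
            got = sorted(o.observation_id
                         for o in kb.observations(patient_id=pid,
                                                  sign_code=sign))
            assert got == expected


# -- abnormal-range axioms --------------------------------------------------

def test_upsert_defines_the_worked_example_region(kb):
    kb.upsert_abnormal_range(perf_axiom(0.5))
    ax = kb.axioms["PerfAN"]
    assert ax.region == (Interval(-math.inf, 0.5, False, False),)


def test_upsert_identical_axiom_keeps_region_but_bumps_version(kb):
    kb.upsert_abnormal_range(perf_axiom(0.5))
    v = kb.version
    region_before = kb.axioms["PerfAN"].region
    kb.upsert_abnormal_range(perf_axiom(0.5))
    assert kb.axioms["PerfAN"].region == region_before
    assert kb.version > v
    assert kb.axioms["PerfAN"].version == 2


def test_upsert_merges_by_union_of_endpoint_regions(kb):
    kb.upsert_abnormal_range(perf_axiom(0.3))
    kb.upsert_abnormal_range(perf_axiom(0.5))
    assert kb.axioms["PerfAN"].region == (Interval(-math.inf, 0.5),)
    # order-insensitivity
    kb2 = make_kb()
    kb2.upsert_abnormal_range(perf_axiom(0.5))
    kb2.upsert_abnormal_range(perf_axiom(0.3))
    assert kb2.axioms["PerfAN"].region == kb.axioms["PerfAN"].region


def test_upsert_rejects_unknown_sign(kb):
    ax = AbnormalRangeAxiom("XAN", "X", (half_line("<", 1.0),))
    with pytest.raises(UnknownReferenceError):
        kb.upsert_abnormal_range(ax)


def test_unnormalized_region_is_rejected():
    with pytest.raises(ConfigError):
        AbnormalRangeAxiom("PerfAN", "Perf",
                           (Interval(0, 2), Interval(1, 3)))


def test_stored_regions_stay_normalized_after_many_upserts(kb):
    rng = np.random.default_rng(7)
    for _ in range(50):
        lo = float(rng.uniform(-10, 10))
        hi = lo + float(rng.uniform(0, 5))
        kb.upsert_abnormal_range(AbnormalRangeAxiom(
            "TempAN", "Temp", normalize_region([Interval(lo, hi)])))
    region = kb.axioms["TempAN"].region
    assert region == normalize_region(region)
    for a, b in zip(region, region[1:]):
        assert a.upper <= b.lower


# -- classification ---------------------------------------------------------

def test_value_on_open_bound_is_not_abnormal(kb):
    kb.upsert_abnormal_range(perf_axiom(0.5))
    assert kb.classify_result("Perf", 0.49)
    assert not kb.classify_result("Perf", 0.5)


def test_sign_without_axiom_is_never_abnormal(kb):
    for v in (-1e9, 0.0, 37.0, 1e9):
        assert not kb.classify_result("Temp", v)


def test_nominal_sign_classification_is_rejected(kb):
    from vitalwatch import VitalSignDefinition
    kb.add_sign(VitalSignDefinition(code="Mood", value_kind="nominal"))
    with pytest.raises(NominalValueError):
        kb.classify_result("Mood", 1.0)


def test_classification_matches_interval_scan_oracle(kb):
    rng = np.random.default_rng(99)
    signs = ["Perf", "Temp", "Pulse"]
    for i in range(10):
        sign = signs[i % len(signs)]
        pieces = [Interval(float(lo), float(lo) + float(rng.uniform(0, 3)),
                           bool(rng.integers(2)), bool(rng.integers(2)))
                  for lo in rng.uniform(-20, 20, size=rng.integers(1, 4))]
        kb.upsert_abnormal_range(AbnormalRangeAxiom(
            f"{sign}AN", sign, normalize_region(pieces)))
    for _ in range(200):
        sign = signs[rng.integers(len(signs))]
        value = float(rng.uniform(-25, 25))
        assert kb.classify_result(sign, value) == \
            classify_by_scan(kb, sign, value)


# -- versioning -------------------------------------------------------------

def test_every_mutation_strictly_increases_version(kb):
    versions = [kb.version]
    kb.add_patient(Patient("P9"))
    versions.append(kb.version)
    kb.add_platform(SensorPlatform("pl1", "P9", "body", {"s1"}))
    versions.append(kb.version)
    kb.assert_observation(Observation("o1", "P1", "Temp", at(0), 37.0))
    versions.append(kb.version)
    kb.upsert_abnormal_range(perf_axiom())
    versions.append(kb.version)
    assert versions == sorted(set(versions))
    assert all(b > a for a, b in zip(versions, versions[1:]))


# -- round-trips ------------------------------------------------------------

def test_turtle_round_trip_of_empty_kb():
    kb = KnowledgeBase()
    back = import_turtle(export_turtle(kb))
    assert back.structurally_equal(kb)
    assert back.observation_count == 0


def test_turtle_round_trip_of_small_kb(kb):
    kb.add_platform(SensorPlatform("pl1", "P1", "body", {"s1", "s2"}))
    kb.upsert_abnormal_range(perf_axiom(0.5))
    kb.assert_observation(Observation("o1", "P1", "Perf", at(0), 0.30000001,
                                      sensor_id="s1"))
    back = import_turtle(export_turtle(kb))
    assert back.structurally_equal(kb)
    assert back.get_observation("o1").value == 0.30000001


def test_turtle_round_trip_of_seeded_synthetic_kb():
    from vitalwatch import (bootstrap_kb, generate_stream,
                            observations_from_frame, monitor_stream,
                            emergency_rule_from_conditions, SignalModel,
                            PlantedEmergency)
    models = [SignalModel("Perf", 1.4, 0.25, period_s=300),
              SignalModel("NBP_Sys", 120, 8, period_s=300)]
    planted = PlantedEmergency("SpO2 LOW PERF",
                               (("Perf", "<", 0.5), ("NBP_Sys", "<", 105.0)),
                               episode_rate_per_day=24)
    obs, _ann = generate_stream(3, models, [planted], duration_hours=6,
                                seed=42)
    kb = bootstrap_kb(["P1", "P2", "P3"])
    kb.add_rule(emergency_rule_from_conditions(
        "SpO2 LOW PERF", [("Perf", "<", 0.5), ("NBP_Sys", "<", 105.0)]))
    monitor_stream(kb, observations_from_frame(obs))
    back = import_turtle(export_turtle(kb))
    assert back.structurally_equal(kb)
    # and the re-import round-trips again
    assert import_turtle(export_turtle(back)).structurally_equal(kb)


def test_malformed_turtle_raises_data_error():
    with pytest.raises(DataError):
        import_turtle("this is not turtle @@@")


def test_unknown_predicate_in_artifact_namespace_is_rejected():
    text = ("@prefix vw: <https://vitalwatch.example/ns#> .\n"
            "vw:kb vw:bogusPredicate 1 .\n")
    with pytest.raises(DataError):
        import_turtle(text)


def test_axiom_json_round_trip(kb):
    kb.upsert_abnormal_range(perf_axiom(0.5))
    kb.upsert_abnormal_range(AbnormalRangeAxiom(
        "TempAN", "Temp", normalize_region([half_line(">", 38.5),
                                            half_line("<", 35.0)])))
    back = axioms_from_json(axioms_to_json(kb.axioms.values()))
    assert {a.class_name: a.region for a in back} == \
        {a.class_name: a.region for a in kb.axioms.values()}
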