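import datetime as dt

import pytest

from vitalwatch import (AbnormalRangeAxiom, KnowledgeBase, Observation,
                        Patient, default_sign_catalog, normalize_region)
from vitalwatch.intervals import half_line

T0 = dt.datetime(2026, 1, 1, tzinfo=dt.timezone.utc)


def at(seconds: float) -> dt.datetime:
    return T0 + dt.timedelta(seconds=seconds)


def make_kb(patients=("P1",)) -> KnowledgeBase:
    kb = KnowledgeBase()
    for sign in default_sign_catalog():
        kb.add_sign(sign)
    for pid in patients:
        kb.add_patient(Patient(patient_id=pid))
    return kb


def perf_axiom(upper=0.5, provenance="learned") -> AbnormalRangeAxiom:
    return AbnormalRangeAxiom(
        class_name="PerfAN", sign_code="Perf",
        region=normalize_region([half_line("<", upper)]),
        provenance=provenance)


@pytest.fixture
def kb() -> KnowledgeBase:
    return make_kb()


@pytest.fixture
def kb_two_patients() -> KnowledgeBase:
    return make_kb(("P1", "P2"))
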