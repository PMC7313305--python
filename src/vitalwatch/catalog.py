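"""Default vital-sign catalog and seed abnormal-range axioms.

The catalog covers the monitor channels the package's worked examples use:
pulse-oximetry derived signals (SpO2, Perf), ventilator airway channels
(AWV, AWF), non-invasive systolic blood pressure, body temperature and
pulse rate.  Plausible ranges are *instrument* plausibility bounds used for
outlier flagging, not clinical reference ranges.

The seed axioms are a deliberately small starting rule base covering the
classic bedside emergencies (low blood pressure, high temperature, low
oxygen saturation, brady-/tachycardia, hypothermia).  They are documented
defaults, clearly marked ``provenance="seed"``; real deployments would
replace them with clinician-authored values.  Each sign is tagged as a
health or contextual attribute for the data-selection step.
"""

from __future__ import annotations

import math

from .intervals import Interval, half_line, normalize_region
from .model import AbnormalRangeAxiom, VitalSignDefinition, axiom_class_name

__all__ = ["default_sign_catalog", "seed_axioms", "ATTRIBUTE_KIND"]

_CATALOG = [
    # code, unit, plausible range (instrument bounds)
    ("SpO2", "%", (0.0, 100.0)),
    ("Perf", "", (0.0, 20.0)),
    ("AWV", "mL", (0.0, 10000.0)),
    ("AWF", "L/min", (0.0, 60.0)),
    ("NBP_Sys", "mmHg", (30.0, 260.0)),
    ("Temp", "degC", (30.0, 45.0)),
    ("Pulse", "bpm", (20.0, 250.0)),
]

#: health vs contextual attribute tag per sign (drives data selection)
ATTRIBUTE_KIND = {code: "health" for code, _, _ in _CATALOG}

_SEED_AXIOMS = [
    # sign, op, constant — the "less blood pressure, high temperature" style
    # starting knowledge, with conventional bedside alarm limits
    ("NBP_Sys", "<", 90.0),
    ("Temp", ">", 38.5),
    ("Temp", "<", 35.0),
    ("SpO2", "<", 90.0),
    ("Pulse", "<", 40.0),
    ("Pulse", ">", 130.0),
]


def default_sign_catalog() -> list[VitalSignDefinition]:
    return [VitalSignDefinition(code=c, unit=u, value_kind="real",
                                default_plausible_range=r)
            for c, u, r in _CATALOG]


def seed_axioms() -> list[AbnormalRangeAxiom]:
    """Starting abnormal-range axioms, one class per sign (regions unioned)."""
    by_sign: dict[str, list[Interval]] = {}
    for sign, op, c in _SEED_AXIOMS:
        by_sign.setdefault(sign, []).append(half_line(op, c))
    return [AbnormalRangeAxiom(class_name=axiom_class_name(sign),
                               sign_code=sign,
                               region=normalize_region(ivs),
                               provenance="seed")
            for sign, ivs in sorted(by_sign.items())]
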