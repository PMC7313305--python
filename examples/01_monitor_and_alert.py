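"""Raise an alarm on a single abnormal vital-sign observation.

Builds a knowledge base with the default sign catalog and the seed
abnormal-range axioms, asserts one low blood-pressure reading, and runs the
generic abnormal-vital-sign rule to a fixpoint.  The derived fact shows the
reading was classified abnormal; the alert carries the evidence.
"""

import datetime as dt

from vitalwatch import (Observation, Patient, KnowledgeBase, abnormal_alert_rule,
                        apply_all, default_sign_catalog, gm_rule, seed_axioms)
from vitalwatch.engine import rule_to_swrl

kb = KnowledgeBase()
for sign in default_sign_catalog():
    kb.add_sign(sign)
kb.add_patient(Patient("P1", name="Pat One"))
for ax in seed_axioms():
    kb.upsert_abnormal_range(ax)

print("generic rule:")
print(" ", rule_to_swrl(gm_rule()))

t = dt.datetime(2026, 1, 1, 8, 30, tzinfo=dt.timezone.utc)
kb.assert_observation(Observation("o1", "P1", "NBP_Sys", t, 82.0))

kb, alerts = apply_all(kb, [gm_rule(), abnormal_alert_rule()])
print("derived facts:", dict(kb.derived))
for a in alerts:
    print(f"alert [{a.label}] patient={a.patient_id} "
          f"evidence={sorted(a.evidence)} at {a.timestamp.isoformat()}")
# The systolic reading of 82 mmHg lies in the seed abnormal region
# (< 90 mmHg), so the vital sign is derived abnormal and one alert fires.
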