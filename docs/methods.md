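# Methods

This note documents the models, parameters and design choices behind
vitalwatch, in the spirit of a statistical package's methods appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Knowledge model

The knowledge base is an ontology-shaped store, not a general RDF triple
store: it models exactly the classes and properties the monitoring loop
touches.  Patients merge an ICNP patient with a FOAF person profile
(identity, birth date, height, weight); SSN-style platforms link each
patient to their sensors through an artifact-owned `hasPlatform` property;
observations follow the SOSA pattern (observation → result, with the result
holding the value); vital signs are catalog entries with a unit, a value
kind (real or nominal) and an optional *plausible instrument range* used
only for outlier flagging.  The borrowed vocabularies (icnp/sosa/ssn/foaf)
are name-compatible references in the Turtle dialect — they are never
imported or reasoned over; full OWL DL semantics is out of scope.

**Abnormal-range axioms.** One axiom per class name, named
deterministically `<Sign>AN` (e.g. `PerfAN`), holding a normalized region:
a sorted tuple of pairwise-disjoint intervals with explicit open/closed
bounds (infinite bounds are always open).  `classify_result(sign, value)`
is true iff the value lies in the union of the regions of that sign's
axioms — this realises the reading that the generic `AbnormalRange` class
is the union of the per-sign abnormal-range classes.

**Upsert = union.** Updating an existing axiom replaces its region by the
union of old and new.  Union is order-insensitive and never forgets a
previously learned abnormal region; the alternative (replacement) would let
a later learning run silently un-learn an earlier emergency.  Repeated
learning on unchanged history is therefore idempotent at the region level.

**Versioning.** Every mutation strictly increments an integer version and
appends a human-readable line to a change log; the alert log is
append-only.  Turtle round-trips are exact up to version counters and
ordering (numeric literals are serialized as `repr` strings because common
Turtle serializers round `xsd:double` literals).

## Rule engine

The rule language is the conjunctive fragment: class atoms, property
atoms, range atoms (abnormal-region membership of a result) and numeric
comparison atoms; consequents either assert a class on a bound individual
or emit a labelled alarm.  Negation, disjunction and other built-ins are
excluded — nothing in the loop needs them, and the positive fragment gives
an order-independent fixpoint for free.

**Matching** enumerates variable bindings over the materialized individuals
(patients, observations, results, per-patient-per-sign vital-sign
individuals).  The join order is chosen greedily by boundness, but the
result set provably equals exhaustive assignment enumeration — the test
suite checks this against an independently written brute-force oracle on
randomized knowledge bases.

**Temporal binding.** A learned alarm rule mixes several signs whose
measurements are never exactly simultaneous.  Each condition binds the
patient's *latest* observation of its sign, and all bound observations must
lie within a co-occurrence window (default 60 s, the default sampling
period) of the patient's most recent measurement.  Monitor alarms describe
an instantaneous state, so "the current value of each channel" is the
faithful semantics; two conditions on the same sign constrain the same
bound observation.

**Batch vs stream evaluation.** `apply_all` is the batch contract: naive
iteration to a fixpoint, alerts deduplicated per (patient, label, evidence)
within the call, no cross-call suppression.  `monitor_stream` ingests a
stream in time order and evaluates alarm rules incrementally with
*edge-triggered* semantics: an alarm fires when its predicate becomes true
for a patient and re-arms only after it has become false — exactly how a
bedside monitor latches an alarm, and the reason one planted episode yields
one alert.  Derived facts are monotone and shared between both modes.

## Data preparation

Flagging tags every cell ok / missing / outlier (outlier = outside the
sign's plausible instrument range) without dropping rows; attribute
selection is an explicit allow-list with a lossless stash (no automatic
relevance criterion is applied — none is defensible at this data scale);
transformation types columns by trying numeric first (thousands separators
`1,234.56` are stripped when the digit grouping matches), then dates
(unified to ISO-8601 UTC), falling back to nominal domains.  A column is
typed when ≥ 90 % of its non-empty cells convert; failing cells become
missing and are reported.  `transform` is idempotent.

**Instance construction.** One positive instance per alarm: for every
real-valued catalog sign, the patient's latest value within the look-back
window (default 60 s) before the alarm; signs with no reading are missing.
NORMAL instances are sampled (seeded) from observation instants at least
`negative_exclusion` (default 600 s) from any of the patient's alarms.
The exclusion zone is deliberately much wider than the window: an
edge-triggered alarm marks only the *onset* of an episode, so instants
shortly after an alarm may still be inside the emergency and must not be
labelled NORMAL.  The negative:positive ratio defaults to 1:1; class
imbalance is controlled here, not by reweighting in the learner.

## Tree learner

A REPTree-style classifier: Shannon information-gain splits, candidate
thresholds at midpoints between consecutive distinct sorted values,
multiway splits on nominal domains, reduced-error pruning on a held-out
fraction (default 0.25, split drawn from the seed).  Tie-breaks are fixed
(lower attribute index, then smaller threshold; leaf majorities break
lexicographically), so learning is fully deterministic given inputs and
seed.  Missing values route to the child with larger training support
(fractional instance weighting is deliberately not implemented — it buys
little on these tables and complicates rule extraction); a value exactly on
a threshold routes to the `>=` branch.  Gains computed on partially missing
attributes are scaled by the known fraction.  Thresholds are reported at
full midpoint precision — constants like `3749.05` in extracted rules are
midpoint artifacts, never rounded.

Path extraction keeps leaves passing a support and purity filter
(`min_support` default 30, `min_purity` default 0.95 — conventional
rule-induction acceptance levels, configurable and logged in every report)
and simplifies conditions per attribute to the tightest bound per
direction.

## Rule synthesis

Each accepted emergency path yields **both** artifacts: the conjunctive
alarm rule (exact alarm semantics, labelled with the leaf label) and the
per-sign axioms (`<` ↦ open upper half-region, `>` ↦ open lower, `<=`/`>=`
closed; equality is rejected — a point is not a range).  Decomposing the
conjunction into per-sign ranges loses the conjunction, which is precisely
why the conjunctive rule is kept alongside: the axioms make the generic
rule *GM* sensitive to each learned region (generic alerts), the rule
preserves the specific labelled alarm.  Learned artifacts carry
`provenance="learned"`; the objective/subjective knowledge distinction is a
metadata tag, not separate stores.  Learned-artifact timestamps use the
knowledge base's latest event time rather than the wall clock so a run is
byte-reproducible given the KB and seed.  Rule ids are content-addressed
(label + conditions hash), so re-learning identical knowledge replaces
rather than duplicates.

## Synthetic data

The simulator emulates multi-channel monitor streams: per-sign Gaussian
baselines with optional linear drift, a sampling period (default 60 s),
missingness (dropped samples) and outlier injection (values beyond the
plausible instrument range).  Planted emergencies schedule
Poisson-distributed, non-overlapping episodes; during an episode every
predicate sign is driven into the predicate region *shrunk by the margin*,
and outside episodes predicate signs are clipped onto the normal side by
the same margin.  For noise-free configurations no value falls inside any
margin band, which is what makes threshold recovery exactly checkable: any
learned threshold inside the band is correct.

Default baselines (SpO2 97±1 %, Perf 1.4±0.25, AWV 4500±200 mL, AWF
15±1.5 L/min, NBP_Sys 120±8 mmHg, Temp 36.8±0.3 °C, Pulse 75±8 bpm) are
*documented fixtures* chosen to sit well clear of the worked-example
thresholds; they are not clinical reference values.  The seed abnormal
ranges (NBP_Sys < 90, Temp > 38.5 or < 35, SpO2 < 90, Pulse < 40 or > 130)
are likewise a starting rule base, marked `provenance="seed"`.

What the simulator does **not** model — and hence what passing tests do not
show about real data: physiological coupling between channels, waveform
artifacts, sensor-specific noise spectra, gradual deterioration (episodes
switch on and off), or label noise in the alarm history beyond the explicit
flip rate.  Episode values can also leave physiological bounds (a clipped
perfusion index may go slightly negative) because the margin guarantee
takes precedence over plausibility.

## Problem sizes and numerical choices

The shipped tests and the acceptance script use desk-scale configurations
chosen to exercise every code path with exact oracles: brute-force matcher
equivalence on knowledge bases of ≤ 8 observations (exhaustive enumeration
is exponential in the number of rule variables), learner recovery on
2000-instance fixtures with margin 0.2 over 20 seeds, and the closed loop
on 3 patients × 24 h at 36 episodes/patient-day over 20 seeds — roughly a
hundred alarms per run, comfortably above the default `min_support` of 30.
Gains below 1e-12 are treated as zero; comparison atoms require finite
constants; NaN values are rejected at ingestion.

## Known limitations

* The rule language has no negation or temporal operators beyond the
  single co-occurrence window; trends ("falling for 10 minutes") cannot be
  expressed.
* Nominal attributes are learnable in the tree but not convertible to
  alarm rules or range axioms; such paths are rejected with a reason in the
  learning report.
* Forward chaining materializes one vital-sign individual per
  (patient, sign); identity of physical sensors is not tracked beyond the
  evidence ids.
* The stream monitor evaluates only latest-observation alarm rules and the
  generic abnormal-range rule incrementally; arbitrary conjunctive rules
  over historical bindings require batch `apply_all`.
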