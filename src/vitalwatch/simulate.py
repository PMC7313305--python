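"""Seeded simulator of multi-patient vital-sign streams with planted
conjunctive emergencies.

Values are Gaussian around a per-sign baseline with optional linear drift;
an emergency episode drives every sign of its predicate beyond the planted
threshold by at least the configured margin, and outside episodes the
predicate signs stay on the normal side by at least the same margin (except
deliberately injected outliers).  This trades physiological realism for an
exact, checkable ground truth: the simulator tests the reasoning loop, not
physiology.  Episode annotations (patient, label, start, end) are returned
alongside the stream and serve as the oracle for alarm recall.

The default baselines are documented fixtures chosen to sit well clear of
the worked-example thresholds; they are not clinical reference values.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import default_sign_catalog
from .errors import ConfigError
from .model import KnowledgeBase, Observation, Patient, SensorPlatform
from .prep import NORMAL_LABEL, LabelledInstanceTable

__all__ = ["SignalModel", "PlantedEmergency", "generate_stream",
           "generate_training_fixture", "default_signal_models",
           "observations_from_frame", "bootstrap_kb", "DEFAULT_START"]

DEFAULT_START = _dt.datetime(2026, 1, 1, tzinfo=_dt.timezone.utc)

Condition = tuple[str, str, float]


@dataclass(frozen=True)
class SignalModel:
    sign_code: str
    mean: float
    sd: float
    period_s: float = 60.0
    drift_per_hour: float = 0.0
    missing_rate: float = 0.0
    outlier_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigError("signal sd must be >= 0")
        if self.period_s <= 0:
            raise ConfigError("sampling period must be > 0")
        for rate in (self.missing_rate, self.outlier_rate):
            if not 0.0 <= rate < 1.0:
                raise ConfigError("rates must lie in [0, 1)")


@dataclass(frozen=True)
class PlantedEmergency:
    label: str
    predicate: tuple[Condition, ...]
    episode_rate_per_day: float = 12.0
    episode_duration_s: float = 240.0
    margin: float = 0.2

    def __post_init__(self) -> None:
        if not self.predicate:
            raise ConfigError("planted predicate must be non-empty")
        if self.margin <= 0:
            raise ConfigError("margin must be > 0")
        for _sign, op, _c in self.predicate:
            if op not in ("<", "<=", ">", ">="):
                raise ConfigError(f"unsupported predicate operator {op!r}")


_DEFAULT_BASELINES = {
    # documented fixture baselines (NOT clinical reference values)
    "SpO2": (97.0, 1.0),
    "Perf": (1.4, 0.25),
    "AWV": (4500.0, 200.0),
    "AWF": (15.0, 1.5),
    "NBP_Sys": (120.0, 8.0),
    "Temp": (36.8, 0.3),
    "Pulse": (75.0, 8.0),
}


def default_signal_models(period_s: float = 60.0) -> list[SignalModel]:
    return [SignalModel(sign_code=c, mean=m, sd=s, period_s=period_s)
            for c, (m, s) in _DEFAULT_BASELINES.items()]


# ---------------------------------------------------------------------------
# predicate geometry
# ---------------------------------------------------------------------------

def _sign_conditions(planted: Sequence[PlantedEmergency]
                     ) -> dict[str, list[tuple[str, float, float]]]:
    """sign -> [(op, constant, margin)] over all planted predicates."""
    out: dict[str, list[tuple[str, float, float]]] = {}
    for em in planted:
        for sign, op, c in em.predicate:
            out.setdefault(sign, []).append((op, float(c), em.margin))
    return out


def _episode_interval(conds: Iterable[Condition],
                      margin: float) -> tuple[float, float]:
    """Feasible value interval during an episode, shrunk by the margin."""
    lo, hi = -math.inf, math.inf
    for _sign, op, c in conds:
        if op in ("<", "<="):
            hi = min(hi, c - margin)
        else:
            lo = max(lo, c + margin)
    if lo > hi:
        raise ConfigError(
            f"planted predicate is unsatisfiable with margin {margin}: "
            f"feasible interval [{lo}, {hi}] is empty")
    return lo, hi


def _sample_in(rng: np.random.Generator, lo: float, hi: float,
               sd: float, size: int) -> np.ndarray:
    if math.isinf(lo) and math.isinf(hi):
        center = 0.0
    elif math.isinf(lo):
        center = hi - 2.0 * max(sd, 1e-9)
    elif math.isinf(hi):
        center = lo + 2.0 * max(sd, 1e-9)
    else:
        center = (lo + hi) / 2.0
    vals = center + rng.normal(0.0, sd, size=size)
    return np.clip(vals, lo if not math.isinf(lo) else None,
                   hi if not math.isinf(hi) else None)


def _normal_side_clip(values: np.ndarray, op: str, c: float,
                      margin: float) -> np.ndarray:
    """Force values onto the normal side of a condition, with margin."""
    if op in ("<", "<="):
        return np.maximum(values, c + margin)
    return np.minimum(values, c - margin)


# ---------------------------------------------------------------------------
# stream generation
# ---------------------------------------------------------------------------

def generate_stream(n_patients: int,
                    models: Sequence[SignalModel],
                    planted: Sequence[PlantedEmergency] = (),
                    duration_hours: float = 24.0,
                    seed: int = 0,
                    start: _dt.datetime = DEFAULT_START
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate observation and annotation tables.

    Returns ``(observations, annotations)``: observations in the ingestion
    CSV schema plus an ``observation_id`` column, annotations with one row
    per planted episode (patient_id, label, start, end).  Identical
    arguments produce identical tables.
    """
    if n_patients < 1:
        raise ConfigError("need at least one patient")
    if not models:
        raise ConfigError("need at least one signal model")
    model_by_sign = {m.sign_code: m for m in models}
    for em in planted:
        for sign, _op, _c in em.predicate:
            if sign not in model_by_sign:
                raise ConfigError(
                    f"planted predicate uses sign {sign!r} with no signal model")
        _episode_interval(em.predicate, em.margin)  # satisfiability check

    rng = np.random.default_rng(seed)
    duration_s = duration_hours * 3600.0
    catalog_ranges = {d.code: d.default_plausible_range
                      for d in default_sign_catalog()}
    patients = [f"P{i + 1}" for i in range(n_patients)]

    ann_rows: list[dict] = []
    episodes: dict[str, list[tuple[float, float, PlantedEmergency]]] = \
        {p: [] for p in patients}
    for pid in patients:
        for em in planted:
            expected = em.episode_rate_per_day * duration_hours / 24.0
            n_ep = int(rng.poisson(expected))
            starts = np.sort(rng.uniform(0.0, max(duration_s - em.episode_duration_s, 0.0),
                                         size=n_ep))
            prev_end = -math.inf
            min_gap = 2.0 * max((m.period_s for m in models), default=60.0)
            for s0 in starts:
                if s0 < prev_end + min_gap:
                    continue
                e0 = s0 + em.episode_duration_s
                if e0 > duration_s:
                    continue
                episodes[pid].append((s0, e0, em))
                prev_end = e0
                ann_rows.append({
                    "patient_id": pid, "label": em.label,
                    "start": (start + _dt.timedelta(seconds=s0)).isoformat(),
                    "end": (start + _dt.timedelta(seconds=e0)).isoformat()})

    sign_conds = _sign_conditions(planted)
    obs_rows: list[dict] = []
    for pid in patients:
        for model in models:
            sign = model.sign_code
            n = int(duration_s // model.period_s)
            if n == 0:
                continue
            t_s = np.arange(n) * model.period_s
            values = (model.mean
                      + model.drift_per_hour * t_s / 3600.0
                      + rng.normal(0.0, model.sd, size=n))
            # keep predicate signs clear of every threshold outside episodes
            for op, c, margin in sign_conds.get(sign, ()):
                values = _normal_side_clip(values, op, c, margin)
            # drive the sign into the planted region during its episodes
            for s0, e0, em in episodes[pid]:
                conds = [cd for cd in em.predicate if cd[0] == sign]
                if not conds:
                    continue
                mask = (t_s >= s0) & (t_s < e0)
                k = int(mask.sum())
                if k:
                    lo, hi = _episode_interval(conds, em.margin)
                    values[mask] = _sample_in(rng, lo, hi, model.sd, k)
            missing = rng.random(n) < model.missing_rate
            outlier = rng.random(n) < model.outlier_rate
            if outlier.any():
                rng_hi = catalog_ranges.get(sign)
                extreme = (rng_hi[1] + 5.0 * max(model.sd, 1.0)
                           if rng_hi else model.mean + 12.0 * max(model.sd, 1.0))
                values[outlier] = extreme
            for i in range(n):
                if missing[i]:
                    continue
                ts = start + _dt.timedelta(seconds=float(t_s[i]))
                obs_rows.append({
                    "patient_id": pid,
                    "sensor_id": f"{pid}-sens-{sign}",
                    "sign_code": sign,
                    "timestamp": ts.isoformat(),
                    "value": repr(float(values[i])),
                    "observation_id": f"{pid}-{sign}-{i:06d}"})

    obs = pd.DataFrame(obs_rows, columns=["patient_id", "sensor_id",
                                          "sign_code", "timestamp", "value",
                                          "observation_id"])
    if len(obs):
        obs = obs.sort_values(["timestamp", "patient_id", "sign_code"],
                              kind="stable").reset_index(drop=True)
    ann = pd.DataFrame(ann_rows, columns=["patient_id", "label",
                                          "start", "end"])
    if len(ann):
        ann = ann.sort_values(["patient_id", "start"],
                              kind="stable").reset_index(drop=True)
    return obs, ann


def observations_from_frame(frame: pd.DataFrame) -> list[Observation]:
    """Materialize Observation objects from a generated stream table."""
    out = []
    for row in frame.itertuples(index=False):
        out.append(Observation(
            observation_id=row.observation_id,
            patient_id=row.patient_id,
            sign_code=row.sign_code,
            timestamp=_dt.datetime.fromisoformat(row.timestamp),
            value=float(row.value),
            sensor_id=row.sensor_id))
    return out


def bootstrap_kb(patient_ids: Iterable[str]) -> KnowledgeBase:
    """KB with the default catalog, the given patients and a body platform each."""
    kb = KnowledgeBase()
    for sign in default_sign_catalog():
        kb.add_sign(sign)
    for pid in patient_ids:
        kb.add_patient(Patient(patient_id=pid))
        kb.add_platform(SensorPlatform(
            platform_id=f"{pid}-platform", owner=pid, kind="body",
            sensor_ids={f"{pid}-monitor"}))
    return kb


# ---------------------------------------------------------------------------
# direct training fixtures for the learner
# ---------------------------------------------------------------------------

def generate_training_fixture(planted: PlantedEmergency,
                              n_per_class: int,
                              noise_label_rate: float = 0.0,
                              seed: int = 0,
                              models: Optional[Sequence[SignalModel]] = None
                              ) -> LabelledInstanceTable:
    """Balanced labelled instances with the planted predicate as ground truth.

    Positive rows satisfy every predicate condition by at least the margin;
    negative rows violate at least one predicate *sign* (the violated signs
    sit on the normal side by at least the margin), so for noise-free
    fixtures no feature value falls inside any margin band.  Labels are
    then flipped independently at ``noise_label_rate``.
    """
    if n_per_class < 1:
        raise ConfigError("n_per_class must be >= 1")
    if models is None:
        models = default_signal_models()
    model_by_sign = {m.sign_code: m for m in models}
    pred_signs = list(dict.fromkeys(s for s, _o, _c in planted.predicate))
    for s in pred_signs:
        if s not in model_by_sign:
            raise ConfigError(f"predicate sign {s!r} has no signal model")
    by_sign: dict[str, list[Condition]] = {
        s: [cd for cd in planted.predicate if cd[0] == s] for s in pred_signs}
    rng = np.random.default_rng(seed)
    feature_columns = [m.sign_code for m in models]

    def baseline(sign: str) -> float:
        m = model_by_sign[sign]
        v = float(rng.normal(m.mean, m.sd))
        for op, c, margin in ((o, c, planted.margin)
                              for s2, o, c in planted.predicate if s2 == sign):
            v = float(_normal_side_clip(np.array([v]), op, c, margin)[0])
        return v

    def emergency_value(sign: str) -> float:
        lo, hi = _episode_interval(by_sign[sign], planted.margin)
        return float(_sample_in(rng, lo, hi, model_by_sign[sign].sd, 1)[0])

    def violation_value(sign: str) -> float:
        op, c, _m = by_sign[sign][0][1], by_sign[sign][0][2], None
        arr = np.array([float(rng.normal(model_by_sign[sign].mean,
                                         model_by_sign[sign].sd))])
        return float(_normal_side_clip(arr, op, c, planted.margin)[0])

    rows: list[dict] = []
    for _ in range(n_per_class):
        row = {s: baseline(s) for s in feature_columns}
        for s in pred_signs:
            row[s] = emergency_value(s)
        row["label"] = planted.label
        rows.append(row)
    for _ in range(n_per_class):
        row = {s: baseline(s) for s in feature_columns}
        while True:
            satisfied = rng.random(len(pred_signs)) < 0.5
            if not satisfied.all():
                break
        for s, sat in zip(pred_signs, satisfied):
            row[s] = emergency_value(s) if sat else violation_value(s)
        row["label"] = NORMAL_LABEL
        rows.append(row)

    frame = pd.DataFrame(rows, columns=feature_columns + ["label"])
    if noise_label_rate > 0.0:
        flip = rng.random(len(frame)) < noise_label_rate
        swapped = frame["label"].map(
            lambda l: NORMAL_LABEL if l == planted.label else planted.label)
        frame.loc[flip, "label"] = swapped[flip]
    return LabelledInstanceTable(frame=frame,
                                 feature_columns=feature_columns)
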