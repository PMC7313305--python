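"""Data preparation: the life cycle from raw records to labelled instances.

Raw sensor/EHR records pass through four steps before learning:

1. *flagging* — every cell is tagged ok / missing / outlier (outlier =
   outside the sign's plausible instrument range); nothing is dropped;
2. *selection* — an explicit allow-list keeps contextual and health
   attributes; removed columns are stashed for lossless restoration;
3. *transformation* — string-to-nominal, date unification to ISO-8601 UTC,
   numeric text (including thousands separators) to reals;
4. *instance construction* — one positive instance per logged alarm
   (features = the patient's latest value of each catalog sign within a
   look-back window), plus NORMAL instances sampled from alarm-free periods.
"""

from __future__ import annotations

import datetime as _dt
import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .model import KnowledgeBase, VitalSignDefinition

__all__ = [
    "RawRecordTable", "CellFlag", "flag_outliers_and_missing",
    "select_attributes", "restore_attributes", "SelectionStash",
    "transform", "LabelledInstanceTable", "build_training_set",
    "write_arff", "NORMAL_LABEL",
]

logger = logging.getLogger("vitalwatch.prep")

NORMAL_LABEL = "NORMAL"

#: numeric text with optional US-style thousands separators ("3,749.05")
_NUMERIC_RE = re.compile(
    r"^[-+]?(\d{1,3}(,\d{3})+|\d+)?(\.\d+)?([eE][-+]?\d+)?$")


@dataclass
class RawRecordTable:
    """Long-format raw records plus per-attribute metadata.

    ``records`` columns: patient_id, timestamp, attribute, value (text);
    ``metadata`` maps attribute name to its catalog definition.
    """

    records: pd.DataFrame
    metadata: dict[str, VitalSignDefinition] = field(default_factory=dict)

    def __post_init__(self) -> None:
        needed = {"patient_id", "timestamp", "attribute", "value"}
        missing = needed - set(self.records.columns)
        if missing:
            raise ConfigError(f"raw record table lacks columns {sorted(missing)}")
        if (self.records["attribute"].astype(str).str.len() == 0).any():
            raise ConfigError("attribute names must be non-empty")


@dataclass(frozen=True)
class CellFlag:
    row: int
    attribute: str
    kind: str  # missing | outlier | unknown


def _is_missing(value) -> bool:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return True
    return isinstance(value, str) and value.strip() == ""


def _parse_real(text: object) -> Optional[float]:
    if isinstance(text, (int, float)) and not isinstance(text, bool):
        return float(text)
    s = str(text).strip()
    if not _NUMERIC_RE.match(s) or s in ("", "+", "-", "."):
        return None
    try:
        return float(s.replace(",", ""))
    except ValueError:
        return None


def flag_outliers_and_missing(
        table: RawRecordTable) -> tuple[RawRecordTable, list[CellFlag]]:
    """Tag every record ok/missing/outlier; no rows are dropped.

    Attributes without metadata are tagged ``unknown`` and a warning is
    logged.  Outliers are values outside the sign's plausible range.
    """
    df = table.records.copy()
    flags: list[CellFlag] = []
    tags: list[str] = []
    warned: set[str] = set()
    for i, (attr, value) in enumerate(zip(df["attribute"], df["value"])):
        meta = table.metadata.get(attr)
        if _is_missing(value):
            tags.append("missing")
            flags.append(CellFlag(i, attr, "missing"))
            continue
        if meta is None:
            tags.append("unknown")
            flags.append(CellFlag(i, attr, "unknown"))
            if attr not in warned:
                logger.warning("attribute %r has no catalog metadata", attr)
                warned.add(attr)
            continue
        if meta.value_kind == "real":
            parsed = _parse_real(value)
            if parsed is None:
                tags.append("missing")
                flags.append(CellFlag(i, attr, "missing"))
                continue
            rng = meta.default_plausible_range
            if rng is not None and not (rng[0] <= parsed <= rng[1]):
                tags.append("outlier")
                flags.append(CellFlag(i, attr, "outlier"))
                continue
        tags.append("ok")
    df["flag"] = tags
    return RawRecordTable(records=df, metadata=table.metadata), flags


# ---------------------------------------------------------------------------
# attribute selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionStash:
    """Everything needed to undo a column selection losslessly."""

    removed: pd.DataFrame
    column_order: list[str]
    missing_selection: list[str]


def select_attributes(frame: pd.DataFrame,
                      selection: Iterable[str]) -> tuple[pd.DataFrame, SelectionStash]:
    """Keep only the selected columns; stash the rest for restoration.

    Names in the selection that are absent from the table are tolerated and
    reported in the stash (and logged); a selection disjoint from the table
    is an error.
    """
    wanted = list(dict.fromkeys(selection))
    if not wanted:
        raise ConfigError("attribute selection must be non-empty")
    present = [c for c in frame.columns if c in wanted]
    absent = [c for c in wanted if c not in frame.columns]
    if not present:
        raise ConfigError(
            f"selection {wanted} shares no columns with the table")
    for name in absent:
        logger.warning("selected attribute %r is not in the table", name)
    removed = [c for c in frame.columns if c not in wanted]
    stash = SelectionStash(removed=frame[removed].copy(),
                           column_order=list(frame.columns),
                           missing_selection=absent)
    return frame[present].copy(), stash


def restore_attributes(reduced: pd.DataFrame,
                       stash: SelectionStash) -> pd.DataFrame:
    out = pd.concat([reduced, stash.removed], axis=1)
    return out[stash.column_order]


# ---------------------------------------------------------------------------
# type/format transformation
# ---------------------------------------------------------------------------

def _try_numeric(series: pd.Series) -> Optional[tuple[pd.Series, list[int]]]:
    parsed = series.map(lambda v: np.nan if _is_missing(v) else _parse_real(v))
    notnull = series.map(lambda v: not _is_missing(v))
    n = int(notnull.sum())
    if n == 0:
        return None
    ok = parsed.notna() & notnull
    if int(ok.sum()) / n < 0.9:
        return None
    failed = sorted(series.index[notnull & parsed.isna()])
    return parsed.astype(float), failed


def _try_datetime(series: pd.Series) -> Optional[tuple[pd.Series, list[int]]]:
    notnull = series.map(lambda v: not _is_missing(v))
    n = int(notnull.sum())
    if n == 0:
        return None
    parsed = pd.to_datetime(series.where(notnull), errors="coerce",
                            format="mixed", utc=True)
    ok = parsed.notna() & notnull
    if int(ok.sum()) / n < 0.9:
        return None
    failed = sorted(series.index[notnull & parsed.isna()])
    return parsed, failed


def transform(frame: pd.DataFrame) -> pd.DataFrame:
    """Type the columns of a table; idempotent.

    Numeric text becomes float (thousands separators removed per the rule
    in :data:`_NUMERIC_RE`), date-like text becomes timezone-aware UTC
    timestamps, everything else becomes a nominal (categorical) domain.
    Cells that fail their column's conversion become missing; their
    coordinates are listed in ``result.attrs["conversion_flags"]``.
    """
    out = {}
    conv_flags: list[CellFlag] = []
    for col in frame.columns:
        s = frame[col]
        if pd.api.types.is_numeric_dtype(s):
            out[col] = s.astype(float)
            continue
        if pd.api.types.is_datetime64_any_dtype(s):
            ts = pd.to_datetime(s, utc=True)
            out[col] = ts
            continue
        if isinstance(s.dtype, pd.CategoricalDtype):
            out[col] = s
            continue
        num = _try_numeric(s)
        if num is not None:
            out[col], failed = num
            conv_flags += [CellFlag(int(i), str(col), "missing") for i in failed]
            continue
        dtm = _try_datetime(s)
        if dtm is not None:
            out[col], failed = dtm
            conv_flags += [CellFlag(int(i), str(col), "missing") for i in failed]
            continue
        cleaned = s.map(lambda v: None if _is_missing(v) else str(v))
        out[col] = pd.Series(pd.Categorical(cleaned), index=s.index)
    result = pd.DataFrame(out, index=frame.index)
    result.attrs["conversion_flags"] = conv_flags
    return result


# ---------------------------------------------------------------------------
# labelled instances
# ---------------------------------------------------------------------------

@dataclass
class LabelledInstanceTable:
    """Feature matrix plus alarm label per row.

    ``frame`` holds one column per feature plus ``label``; ``provenance``
    records which patient and instant each row was cut from.
    """

    frame: pd.DataFrame
    feature_columns: list[str]
    provenance: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if "label" not in self.frame.columns:
            raise ConfigError("instance table needs a 'label' column")
        if self.frame["label"].isna().any():
            raise ConfigError("instance labels must not be missing")

    @property
    def features(self) -> pd.DataFrame:
        return self.frame[self.feature_columns]

    @property
    def labels(self) -> pd.Series:
        return self.frame["label"]

    def __len__(self) -> int:
        return len(self.frame)


def build_training_set(kb: KnowledgeBase,
                       window: float = 60.0,
                       *,
                       negative_ratio: float = 1.0,
                       negative_exclusion: float = 600.0,
                       seed: int = 0) -> LabelledInstanceTable:
    """Labelled instances from the alarm history.

    One positive instance per logged alert: for each real-valued catalog
    sign, the patient's latest value within ``window`` seconds before the
    alert (missing if none); the label is the alarm label.  NORMAL
    instances are sampled (seeded, deterministic) from observation instants
    at least ``negative_exclusion`` seconds away from any of the patient's
    alerts — an alert marks only the *onset* of an episode, so a generous
    exclusion zone keeps in-episode instants out of the NORMAL class.
    Alerts with no observation in the window are dropped with a warning.
    """
    signs = [c for c, d in kb.sign_catalog.items() if d.value_kind == "real"]
    rows: list[dict] = []
    prov: list[dict] = []

    def cut_features(pid: str, t: _dt.datetime) -> tuple[dict, int]:
        feats = {}
        n_found = 0
        for sign in signs:
            o = kb.latest_observation(pid, sign, at=t, window=window)
            if o is None:
                feats[sign] = np.nan
            else:
                feats[sign] = o.value
                n_found += 1
        return feats, n_found

    alerts = sorted(kb.alert_log, key=lambda a: (a.timestamp, a.alert_id))
    for alert in alerts:
        feats, n_found = cut_features(alert.patient_id, alert.timestamp)
        if n_found == 0:
            logger.warning("alert %s has no observations within %.0f s; "
                           "instance dropped", alert.alert_id, window)
            continue
        rows.append({**feats, "label": alert.label})
        prov.append({"patient_id": alert.patient_id,
                     "time": alert.timestamp, "source": alert.alert_id})
    n_pos = len(rows)

    alert_times: dict[str, list[_dt.datetime]] = {}
    for a in kb.alert_log:
        alert_times.setdefault(a.patient_id, []).append(a.timestamp)
    candidates: list[tuple[_dt.datetime, str]] = []
    seen: set[tuple[str, _dt.datetime]] = set()
    for o in kb.observations():
        key = (o.patient_id, o.timestamp)
        if key in seen:
            continue
        seen.add(key)
        near_alert = any(
            abs((o.timestamp - t).total_seconds()) <= negative_exclusion
            for t in alert_times.get(o.patient_id, ()))
        if not near_alert:
            candidates.append((o.timestamp, o.patient_id))
    candidates.sort()
    n_neg = min(int(round(negative_ratio * n_pos)), len(candidates))
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(len(candidates), size=n_neg, replace=False)) \
        if n_neg else []
    for idx in chosen:
        t, pid = candidates[idx]
        feats, n_found = cut_features(pid, t)
        if n_found == 0:
            continue
        rows.append({**feats, "label": NORMAL_LABEL})
        prov.append({"patient_id": pid, "time": t, "source": "sampled"})

    frame = pd.DataFrame(rows, columns=signs + ["label"])
    return LabelledInstanceTable(frame=frame, feature_columns=signs,
                                 provenance=pd.DataFrame(
                                     prov, columns=["patient_id", "time",
                                                    "source"]))


# ---------------------------------------------------------------------------
# ARFF export (interoperability with common DM workbenches)
# ---------------------------------------------------------------------------

def write_arff(table: LabelledInstanceTable, fp: IO[str],
               relation: str = "vitalwatch-alarms") -> None:
    fp.write(f"@RELATION {relation}\n\n")
    frame = table.frame
    for col in table.feature_columns + ["label"]:
        s = frame[col]
        if col != "label" and pd.api.types.is_numeric_dtype(s):
            fp.write(f"@ATTRIBUTE {col} NUMERIC\n")
        else:
            domain = sorted({str(v) for v in s.dropna().unique()})
            joined = ",".join(domain)
            fp.write(f"@ATTRIBUTE {col} {{{joined}}}\n")
    fp.write("\n@DATA\n")
    for _, row in frame.iterrows():
        cells = []
        for col in table.feature_columns + ["label"]:
            v = row[col]
            if _is_missing(v):
                cells.append("?")
            elif isinstance(v, float):
                cells.append(repr(v))
            else:
                cells.append(str(v))
        fp.write(",".join(cells) + "\n")
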