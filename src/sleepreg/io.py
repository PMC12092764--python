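"""Tabular I/O for actigraphy epoch exports, sleep diaries and cohort metadata.

All formats are plain CSV. Epoch files carry one row per 30-s epoch with an
ISO-8601 timestamp and a non-negative activity count (device counts, peak
detection mode); optional columns carry ambient light (lux) and an event-marker
flag. A :class:`CsvDialect` remaps column names so that real device exports can
be adapted without code changes. Timestamps are local clock time throughout; no
time-zone arithmetic is performed.

Missing epochs are never dropped: a gap in the file is filled on the uniform
30-s grid and marked ``wear=False`` so that day-grid geometry downstream is
preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from datetime import date, time
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "RangeError",
    "CsvDialect",
    "ActigraphySeries",
    "SleepDiary",
    "ParticipantRecord",
    "read_epoch_csv",
    "write_epoch_csv",
    "read_sleep_diary",
    "write_sleep_diary",
    "read_cohort_metadata",
    "write_cohort_metadata",
    "write_results_table",
    "read_results_table",
    "RESULT_COLUMNS",
]

SECONDS_PER_DAY = 86400


class FormatError(ValueError):
    """A file is structurally unusable (bad spacing, duplicate keys, ...)."""


class RangeError(ValueError):
    """A value falls outside its documented range."""


@dataclass
class CsvDialect:
    """Column-name mapping for epoch CSV exports.

    The defaults describe the package's own export format; point the fields at
    the corresponding column headers to consume a third-party export.
    """

    timestamp: str = "timestamp"
    activity: str = "activity"
    light: str | None = "light"
    event_marker: str | None = "marker"


@dataclass
class ActigraphySeries:
    """A uniform 30-s epoch record stream for one participant.

    Attributes
    ----------
    participant_id : str
        Opaque identifier.
    start_time : pandas.Timestamp
        Local clock time of the first epoch.
    activity : ndarray of int
        Non-negative device counts, one per epoch.
    epoch_length : int
        Epoch duration in seconds; must divide 86400 exactly.
    light : ndarray of float, optional
        Ambient light in lux.
    event_marker : ndarray of bool
        Participant-pressed marker flags.
    wear : ndarray of bool
        False where the device was off-wrist or no data were recorded.
    """

    participant_id: str
    start_time: pd.Timestamp
    activity: np.ndarray
    epoch_length: int = 30
    light: np.ndarray | None = None
    event_marker: np.ndarray | None = None
    wear: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        self.activity = np.asarray(self.activity)
        if self.activity.ndim != 1 or self.activity.size < 1:
            raise ValueError("activity must be a non-empty 1-d sequence")
        if not np.all(np.isfinite(self.activity)):
            raise ValueError("activity values must be finite")
        if np.any(self.activity < 0):
            raise ValueError("activity values must be >= 0")
        self.activity = self.activity.astype(np.int64)
        if SECONDS_PER_DAY % int(self.epoch_length) != 0:
            raise ValueError(
                f"epoch_length {self.epoch_length} s does not divide 86400"
            )
        n = self.activity.size
        if self.light is not None:
            self.light = np.asarray(self.light, dtype=float)
        if self.event_marker is None:
            self.event_marker = np.zeros(n, dtype=bool)
        else:
            self.event_marker = np.asarray(self.event_marker, dtype=bool)
        if self.wear is None:
            self.wear = np.ones(n, dtype=bool)
        else:
            self.wear = np.asarray(self.wear, dtype=bool)
        for name in ("light", "event_marker", "wear"):
            arr = getattr(self, name)
            if arr is not None and arr.shape != (n,):
                raise ValueError(f"{name} length {arr.shape} != activity length {n}")

    @property
    def n_epochs(self) -> int:
        return int(self.activity.size)

    @property
    def epochs_per_day(self) -> int:
        return SECONDS_PER_DAY // int(self.epoch_length)

    def times(self) -> pd.DatetimeIndex:
        """Timestamps of every epoch on the uniform grid."""
        step = pd.Timedelta(seconds=int(self.epoch_length))
        return pd.DatetimeIndex(self.start_time + step * np.arange(self.n_epochs))

    def replace(self, **kwargs) -> "ActigraphySeries":
        """Return a copy with the given fields replaced (arrays are copied)."""
        state = {f.name: getattr(self, f.name) for f in fields(self)}
        for key in ("activity", "light", "event_marker", "wear"):
            if state[key] is not None and key not in kwargs:
                state[key] = state[key].copy()
        state.update(kwargs)
        return ActigraphySeries(**state)


@dataclass
class SleepDiary:
    """Per-night attempted-sleep / final-wake clock times for one participant.

    ``nights`` has one row per calendar night with columns ``date``
    (:class:`datetime.date` of the evening the night starts),
    ``attempted_sleep`` and ``final_wake`` (:class:`datetime.time` or None).
    The attempted-sleep time precedes the final wake on the wrapped 24-h clock.
    """

    participant_id: str
    nights: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["date", "attempted_sleep", "final_wake"]
        )
    )

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.nights).reset_index(drop=True)
        for col in ("date", "attempted_sleep", "final_wake"):
            if col not in df.columns:
                raise ValueError(f"diary missing column {col!r}")
        if df["date"].duplicated().any():
            dup = df.loc[df["date"].duplicated(), "date"].iloc[0]
            raise FormatError(f"duplicate diary date {dup}")
        for _, row in df.iterrows():
            a, w = row["attempted_sleep"], row["final_wake"]
            if a is not None and w is not None and a == w:
                raise ValueError(
                    f"attempted sleep equals final wake on {row['date']}"
                )
        self.nights = df.sort_values("date", kind="stable").reset_index(drop=True)

    def window_for(self, night_date: date) -> tuple[time, time] | None:
        """Return (attempted_sleep, final_wake) for a night, if fully present."""
        rows = self.nights[self.nights["date"] == night_date]
        if rows.empty:
            return None
        a = rows.iloc[0]["attempted_sleep"]
        w = rows.iloc[0]["final_wake"]
        if a is None or w is None:
            return None
        return a, w


_QUESTIONNAIRE_RANGES = {
    "sci": (0, 32, "range 0–32"),
    "phq8": (0, 24, "range 0–24"),
    "mrs": (0, 6, "range 0–6"),
}


@dataclass
class ParticipantRecord:
    """Covariates and questionnaire scores for one participant.

    ``group`` is 0 for controls and 1 for stroke survivors. ``sex`` is
    ``"male"`` or ``"female"``. Questionnaire fields are optional and validated
    against their instrument ranges: SCI 0-32 (higher = better sleep), PHQ-8
    0-24 (higher = more depressive symptoms), mRS 0-6, SF-SIS max 100.
    """

    participant_id: str
    group: int
    age: float
    sex: str
    sci: float | None = None
    phq8: float | None = None
    mrs: float | None = None
    sfsis: float | None = None
    time_since_stroke: float | None = None

    def __post_init__(self) -> None:
        if self.group not in (0, 1):
            raise RangeError(f"group must be 0 (control) or 1 (stroke), got {self.group}")
        if self.sex not in ("male", "female"):
            raise RangeError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not np.isfinite(self.age) or self.age < 0:
            raise RangeError(f"age must be a non-negative number, got {self.age}")
        for name, (lo, hi, label) in _QUESTIONNAIRE_RANGES.items():
            val = getattr(self, name)
            if val is not None and not lo <= val <= hi:
                raise RangeError(f"{name}={val} outside {label}")
        if self.sfsis is not None and self.sfsis > 100:
            raise RangeError(f"sfsis={self.sfsis} exceeds max score 100")

    @property
    def is_female(self) -> bool:
        return self.sex == "female"


# ---------------------------------------------------------------------------
# epoch CSV


def read_epoch_csv(
    path: str | Path,
    dialect: CsvDialect | None = None,
    participant_id: str | None = None,
    epoch_length: int = 30,
) -> ActigraphySeries:
    """Read an epoch export and return a gap-filled uniform series.

    Rows must sit on a strict ``epoch_length`` grid relative to the first
    timestamp; epochs absent from the file are filled with zero activity and
    ``wear=False``. Present epochs are never altered.

    Raises
    ------
    FormatError
        If a timestamp cannot be parsed (the offending row is named), rows are
        not resolvable to the grid, or a timestamp is duplicated.
    """
    path = Path(path)
    dialect = dialect or CsvDialect()
    df = pd.read_csv(path)
    for col in (dialect.timestamp, dialect.activity):
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing required column {col!r}")
    ts = pd.to_datetime(df[dialect.timestamp], errors="coerce")
    if ts.isna().any():
        row = int(np.flatnonzero(ts.isna().to_numpy())[0])
        raise FormatError(
            f"{path.name}: malformed timestamp "
            f"{df[dialect.timestamp].iloc[row]!r} at data row {row + 1}"
        )
    step = pd.Timedelta(seconds=epoch_length)
    offsets = (ts - ts.iloc[0]) / step
    rounded = offsets.round()
    if not np.allclose(offsets, rounded, atol=1e-9):
        row = int(np.flatnonzero(~np.isclose(offsets, rounded, atol=1e-9))[0])
        raise FormatError(
            f"{path.name}: timestamp at data row {row + 1} is not on the "
            f"{epoch_length}-s grid"
        )
    idx = rounded.astype(np.int64).to_numpy()
    if np.any(np.diff(idx) <= 0):
        row = int(np.flatnonzero(np.diff(idx) <= 0)[0]) + 1
        raise FormatError(
            f"{path.name}: timestamps not strictly increasing at data row {row + 1}"
        )
    n = int(idx[-1]) + 1
    activity = np.zeros(n, dtype=np.int64)
    wear = np.zeros(n, dtype=bool)
    activity[idx] = pd.to_numeric(df[dialect.activity]).to_numpy()
    wear[idx] = True
    if "wear" in df.columns:
        wear[idx] &= df["wear"].astype(bool).to_numpy()

    light = None
    if dialect.light and dialect.light in df.columns:
        light = np.zeros(n, dtype=float)
        light[idx] = pd.to_numeric(df[dialect.light]).to_numpy()
    marker = np.zeros(n, dtype=bool)
    if dialect.event_marker and dialect.event_marker in df.columns:
        marker[idx] = df[dialect.event_marker].astype(bool).to_numpy()

    return ActigraphySeries(
        participant_id=participant_id or path.stem,
        start_time=ts.iloc[0],
        activity=activity,
        epoch_length=epoch_length,
        light=light,
        event_marker=marker,
        wear=wear,
    )


def write_epoch_csv(series: ActigraphySeries, path: str | Path) -> None:
    """Write a series as an epoch CSV (one row per epoch, worn or not)."""
    out = pd.DataFrame(
        {
            "timestamp": series.times().strftime("%Y-%m-%dT%H:%M:%S"),
            "activity": series.activity,
        }
    )
    if series.light is not None:
        out["light"] = series.light
    out["marker"] = series.event_marker.astype(int)
    out["wear"] = series.wear.astype(int)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# sleep diary


def _parse_clock(value) -> time | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    if isinstance(value, time):
        return value
    parsed = pd.to_datetime(str(value), format="%H:%M", errors="coerce")
    if pd.isna(parsed):
        parsed = pd.to_datetime(str(value), errors="coerce")
    if pd.isna(parsed):
        raise FormatError(f"malformed clock time {value!r}")
    return parsed.time()


def read_sleep_diary(path: str | Path, participant_id: str | None = None) -> SleepDiary:
    """Read a 7-night-style diary CSV (date, attempted_sleep, final_wake).

    Empty cells are preserved as missing; rows are returned sorted by date.
    Duplicate dates raise :class:`FormatError`.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    cols = {c.lower().strip(): c for c in df.columns}
    for needed in ("date", "attempted_sleep", "final_wake"):
        if needed not in cols:
            raise FormatError(f"{path.name}: missing column {needed!r}")
    dates = pd.to_datetime(df[cols["date"]], errors="coerce")
    if dates.isna().any():
        row = int(np.flatnonzero(dates.isna().to_numpy())[0])
        raise FormatError(f"{path.name}: malformed date at data row {row + 1}")
    nights = pd.DataFrame(
        {
            "date": [d.date() for d in dates],
            "attempted_sleep": [_parse_clock(v) for v in df[cols["attempted_sleep"]]],
            "final_wake": [_parse_clock(v) for v in df[cols["final_wake"]]],
        }
    )
    return SleepDiary(participant_id=participant_id or path.stem, nights=nights)


def write_sleep_diary(diary: SleepDiary, path: str | Path) -> None:
    out = diary.nights.copy()
    out["date"] = [d.isoformat() for d in out["date"]]
    for col in ("attempted_sleep", "final_wake"):
        out[col] = [t.strftime("%H:%M") if t is not None else "" for t in out[col]]
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# cohort metadata

_GROUP_CODES = {"control": 0, "stroke": 1, "0": 0, "1": 1}
_SEX_CODES = {"m": "male", "male": "male", "f": "female", "female": "female"}

_META_COLUMNS = [
    "participant_id",
    "group",
    "age",
    "sex",
    "sci",
    "phq8",
    "mrs",
    "sfsis",
    "time_since_stroke",
]


def read_cohort_metadata(path: str | Path) -> list[ParticipantRecord]:
    """Read one-row-per-participant metadata; out-of-range values are rejected."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("participant_id", "group", "age", "sex"):
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing column {col!r}")
    records = []
    for _, row in df.iterrows():
        group_raw = str(row["group"]).strip().lower()
        if group_raw not in _GROUP_CODES:
            raise FormatError(f"{path.name}: unknown group {row['group']!r}")
        sex_raw = str(row["sex"]).strip().lower()
        if sex_raw not in _SEX_CODES:
            raise FormatError(f"{path.name}: unknown sex {row['sex']!r}")

        def opt(col: str) -> float | None:
            if col not in df.columns or pd.isna(row[col]):
                return None
            return float(row[col])

        records.append(
            ParticipantRecord(
                participant_id=str(row["participant_id"]),
                group=_GROUP_CODES[group_raw],
                age=float(row["age"]),
                sex=_SEX_CODES[sex_raw],
                sci=opt("sci"),
                phq8=opt("phq8"),
                mrs=opt("mrs"),
                sfsis=opt("sfsis"),
                time_since_stroke=opt("time_since_stroke"),
            )
        )
    return records


def write_cohort_metadata(records: Sequence[ParticipantRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        rows.append(
            {
                "participant_id": rec.participant_id,
                "group": "stroke" if rec.group == 1 else "control",
                "age": rec.age,
                "sex": rec.sex,
                "sci": rec.sci,
                "phq8": rec.phq8,
                "mrs": rec.mrs,
                "sfsis": rec.sfsis,
                "time_since_stroke": rec.time_since_stroke,
            }
        )
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# results table

RESULT_COLUMNS = [
    "participant_id",
    "sri",
    "regularity_class",
    "n_days",
    "valid",
    "exclusion_reasons",
    "tst_min",
    "waso_min",
    "sleep_efficiency_pct",
    "fragmentation_index",
    "avg_sleep_per_24h_min",
]


def write_results_table(results: pd.DataFrame, path: str | Path) -> None:
    """Write per-participant metrics + SRI with a deterministic column order.

    Columns from :data:`RESULT_COLUMNS` come first (missing ones are skipped);
    any extra columns follow in sorted order. Empty optional fields serialise
    as empty cells. Raises :class:`ValueError` on an empty table.
    """
    if len(results) == 0:
        raise ValueError("results table is empty")
    lead = [c for c in RESULT_COLUMNS if c in results.columns]
    rest = sorted(c for c in results.columns if c not in lead)
    results[lead + rest].to_csv(path, index=False, float_format="%.10g")


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
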