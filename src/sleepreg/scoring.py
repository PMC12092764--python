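"""Per-epoch sleep/wake scoring from wrist activity counts.

The scorer is the classic weighted-moving-window family used for wrist
actigraphy: each epoch's score is a scaled weighted sum of activity counts in
a window of neighbouring epochs, and the epoch is classified as sleep when the
score falls below a threshold. The UCSD variant of this family is selected by
its tap weights and by a scaling factor of 0.10; taps are configuration data
(see :class:`ScoringConfig`), so any published tap set can be supplied.

Because count scorers have high sensitivity but low specificity (they call
sleep too readily), Webster's rescoring rules are applied afterwards: short
sleep runs following, or sandwiched between, long wake runs are rescored as
wake. Rescored epochs are tracked explicitly so that triggers are always
evaluated against the scorer's own output, which makes rescoring idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta

import numpy as np
import pandas as pd

from .io import ActigraphySeries, SleepDiary

__all__ = [
    "SLEEP",
    "WAKE",
    "MISSING",
    "ScoringConfig",
    "PeriodConfig",
    "SleepWakeSeries",
    "SleepPeriod",
    "score_ucsd",
    "apply_webster_rescoring",
    "detect_nonwear",
    "delimit_sleep_periods",
]

SLEEP = np.int8(1)
WAKE = np.int8(0)
MISSING = np.int8(-1)


def _default_weights() -> np.ndarray:
    # Seven-minute weighted window of the classic count scorers (four minutes
    # of history, the scored minute, two minutes of lookahead), resampled to
    # 30-s epochs by splitting each one-minute weight over its two taps.
    minute_weights = [0.106, 0.054, 0.058, 0.076, 0.230, 0.074, 0.067]
    return np.repeat(np.asarray(minute_weights) / 2.0, 2)


@dataclass
class ScoringConfig:
    """Weights, threshold and rescoring rules for the activity scorer.

    Parameters
    ----------
    weights : ndarray
        Finite tap weights over a window of epochs; ``center`` is the index of
        the scored epoch inside the window (the window may be asymmetric).
    scale_factor : float
        Multiplier applied to the weighted sum (0.10 for the UCSD variant).
    threshold : float
        Score below this value classifies the epoch as sleep.
    rescore_after_wake : sequence of (trigger, rescore) minute pairs
        After at least ``trigger`` minutes of wake, the next ``rescore``
        minutes of scored sleep are rescored wake. Applied in the given order;
        the default lists the strongest trigger first so that exactly one rule
        fires per sleep run.
    rescore_sandwich : sequence of (max_sleep, min_flank) minute pairs
        A sleep run of at most ``max_sleep`` minutes flanked on both sides by
        wake runs of at least ``min_flank`` minutes is rescored wake.
    epochs_per_minute : int
        Minute-to-epoch conversion (2 at 30-s epochs).
    """

    weights: np.ndarray = field(default_factory=_default_weights)
    center: int = 8
    scale_factor: float = 0.10
    threshold: float = 1.0
    rescore_after_wake: tuple[tuple[float, float], ...] = ((15, 4), (10, 3), (4, 1))
    rescore_sandwich: tuple[tuple[float, float], ...] = ((6, 10), (10, 20))
    epochs_per_minute: int = 2

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.size == 0 or not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be a non-empty finite vector")
        if not 0 <= self.center < self.weights.size:
            raise ValueError("center must index into the weight window")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be > 0")
        for a, b in tuple(self.rescore_after_wake) + tuple(self.rescore_sandwich):
            if a <= 0 or b <= 0:
                raise ValueError("rescoring rule durations must be > 0")
        if self.epochs_per_minute < 1:
            raise ValueError("epochs_per_minute must be >= 1")


@dataclass
class SleepWakeSeries:
    """Per-epoch sleep(1)/wake(0)/missing(-1) states aligned to a series."""

    participant_id: str
    start_time: pd.Timestamp
    states: np.ndarray
    epoch_length: int = 30
    provenance: str = "ucsd"
    rescored: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        self.start_time = pd.Timestamp(self.start_time)
        if not np.isin(self.states, (SLEEP, WAKE, MISSING)).all():
            raise ValueError("states must be in {1, 0, -1}")
        if self.rescored is not None:
            self.rescored = np.asarray(self.rescored, dtype=bool)
            if self.rescored.shape != self.states.shape:
                raise ValueError("rescored mask must match states length")

    @property
    def n_epochs(self) -> int:
        return int(self.states.size)

    def times(self) -> pd.DatetimeIndex:
        step = pd.Timedelta(seconds=int(self.epoch_length))
        return pd.DatetimeIndex(self.start_time + step * np.arange(self.n_epochs))


@dataclass
class SleepPeriod:
    """One nocturnal sleep period: [onset, offset] inclusive epoch indices."""

    night_date: date
    onset: int
    offset: int
    onset_time: pd.Timestamp
    offset_time: pd.Timestamp
    source: str  # 'diary' | 'markers' | 'fallback'

    def __post_init__(self) -> None:
        if self.onset >= self.offset:
            raise ValueError("onset must precede offset")


def score_ucsd(series: ActigraphySeries, cfg: ScoringConfig | None = None) -> SleepWakeSeries:
    """Score every worn epoch sleep/wake with the weighted-window algorithm.

    The score of epoch ``t`` is ``scale_factor * sum_k weights[k] *
    activity[t + k - center]``; out-of-range and non-worn taps contribute zero
    (zero padding), so edge epochs of week-long recordings are retained.
    Epochs with ``wear=False`` stay missing.
    """
    cfg = cfg or ScoringConfig()
    if not series.wear.any():
        raise ValueError("no wearable epochs in series")
    a = series.activity.astype(float) * series.wear
    left = cfg.center
    right = cfg.weights.size - 1 - cfg.center
    padded = np.pad(a, (left, right))
    scores = cfg.scale_factor * np.correlate(padded, cfg.weights, mode="valid")
    states = np.where(scores < cfg.threshold, SLEEP, WAKE).astype(np.int8)
    states[~series.wear] = MISSING
    return SleepWakeSeries(
        participant_id=series.participant_id,
        start_time=series.start_time,
        states=states,
        epoch_length=series.epoch_length,
        provenance="ucsd",
    )


def _runs(states: np.ndarray) -> list[tuple[int, int, int]]:
    """Run-length encode states as (value, start, length)."""
    arr = np.asarray(states)
    n = arr.size
    if n == 0:
        return []
    change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    return [(int(arr[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def apply_webster_rescoring(
    states: SleepWakeSeries, cfg: ScoringConfig | None = None
) -> SleepWakeSeries:
    """Apply Webster's rescoring rules; only sleep→wake flips are possible.

    Trigger and flank runs count only epochs that were scored wake by the
    activity scorer itself (rescored epochs carry a mask and never extend a
    trigger), and missing epochs break runs. Under the default rule set the
    operation is idempotent on its own output.
    """
    cfg = cfg or ScoringConfig()
    epm = cfg.epochs_per_minute
    st = states.states.copy()
    rescored = (
        states.rescored.copy()
        if states.rescored is not None
        else np.zeros(st.size, dtype=bool)
    )
    n = st.size

    # after-wake rules: after >= trigger min of wake, rescore the next
    # `res` min of sleep; the remainder of the sleep run is left alone.
    for trig_min, res_min in cfg.rescore_after_wake:
        trig = int(round(trig_min * epm))
        res = int(round(res_min * epm))
        run = 0
        i = 0
        while i < n:
            s = st[i]
            if s == WAKE:
                run = run + 1 if not rescored[i] else 0
                i += 1
            elif s == MISSING:
                run = 0
                i += 1
            else:  # sleep
                if run >= trig:
                    j = i
                    while j < min(i + res, n) and st[j] == SLEEP:
                        st[j] = WAKE
                        rescored[j] = True
                        j += 1
                    while j < n and st[j] == SLEEP:
                        j += 1
                    i = j
                else:
                    i += 1
                run = 0

    # sandwich rules: short sleep runs flanked by long wake runs become wake.
    for max_sleep_min, flank_min in cfg.rescore_sandwich:
        max_sleep = int(round(max_sleep_min * epm))
        flank = int(round(flank_min * epm))
        runs = _runs(st)
        to_rescore: list[tuple[int, int]] = []
        for k, (value, start, length) in enumerate(runs):
            if value != SLEEP or length > max_sleep:
                continue
            if k == 0 or k == len(runs) - 1:
                continue
            lval, lstart, llen = runs[k - 1]
            rval, rstart, rlen = runs[k + 1]
            if lval != WAKE or rval != WAKE:
                continue
            lbase = int(np.sum(~rescored[lstart : lstart + llen]))
            rbase = int(np.sum(~rescored[rstart : rstart + rlen]))
            if lbase >= flank and rbase >= flank:
                to_rescore.append((start, length))
        for start, length in to_rescore:
            st[start : start + length] = WAKE
            rescored[start : start + length] = True

    return SleepWakeSeries(
        participant_id=states.participant_id,
        start_time=states.start_time,
        states=st,
        epoch_length=states.epoch_length,
        provenance="ucsd+webster",
        rescored=rescored,
    )


def detect_nonwear(series: ActigraphySeries, min_zero_run: float = 90.0) -> ActigraphySeries:
    """Mark maximal zero-activity runs of at least ``min_zero_run`` minutes
    as non-wear (in addition to any device wear flags). Shorter zero runs are
    untouched, and activity values are never altered."""
    if min_zero_run <= 0:
        raise ValueError("min_zero_run must be > 0")
    min_epochs = int(round(min_zero_run * 60.0 / series.epoch_length))
    wear = series.wear.copy()
    zero = series.activity == 0
    for value, start, length in _runs(zero.astype(np.int8)):
        if value == 1 and length >= min_epochs:
            wear[start : start + length] = False
    return series.replace(wear=wear)


@dataclass
class PeriodConfig:
    """Search parameters for nocturnal sleep-period delimitation."""

    diary_tolerance_min: float = 60.0
    min_sleep_run_min: float = 10.0
    marker_search_start: time = time(18, 0)  # evening, night-date day
    marker_search_end: time = time(12, 0)  # morning, next day
    fallback_evening: time = time(20, 0)
    fallback_morning: time = time(10, 0)
    min_marker_span_hours: float = 2.0


def _night_window(
    states: SleepWakeSeries,
    night: date,
    diary: SleepDiary | None,
    series: ActigraphySeries | None,
    cfg: PeriodConfig,
) -> tuple[pd.Timestamp, pd.Timestamp, str] | None:
    tol = pd.Timedelta(minutes=cfg.diary_tolerance_min)
    nxt = night + timedelta(days=1)
    if diary is not None:
        window = diary.window_for(night)
        if window is not None:
            a, w = window
            sleep_dt = pd.Timestamp(datetime.combine(night if a >= time(12, 0) else nxt, a))
            wake_dt = pd.Timestamp(datetime.combine(nxt, w))
            if wake_dt > sleep_dt:
                return sleep_dt - tol, wake_dt + tol, "diary"
    if series is not None and series.event_marker is not None and series.event_marker.any():
        times = series.times()
        lo = pd.Timestamp(datetime.combine(night, cfg.marker_search_start))
        hi = pd.Timestamp(datetime.combine(nxt, cfg.marker_search_end))
        mask = series.event_marker & (times >= lo) & (times <= hi)
        hits = times[mask]
        if len(hits) >= 2 and (hits[-1] - hits[0]) >= pd.Timedelta(
            hours=cfg.min_marker_span_hours
        ):
            return hits[0], hits[-1], "markers"
    return (
        pd.Timestamp(datetime.combine(night, cfg.fallback_evening)),
        pd.Timestamp(datetime.combine(nxt, cfg.fallback_morning)),
        "fallback",
    )


def delimit_sleep_periods(
    states: SleepWakeSeries,
    diary: SleepDiary | None = None,
    series: ActigraphySeries | None = None,
    cfg: PeriodConfig | None = None,
) -> list[SleepPeriod]:
    """Delimit one nocturnal sleep period per calendar night.

    The per-night search window is, in order of preference: the diary interval
    widened by ``diary_tolerance_min``; the span between evening and morning
    event markers; a fixed nocturnal fallback window. Within the window the
    onset is the start of the first sustained sleep run (>=
    ``min_sleep_run_min``) and the offset the end of the last; nights without
    a sustained run yield no period.
    """
    cfg = cfg or PeriodConfig()
    times = states.times()
    if times[-1] - times[0] < pd.Timedelta(hours=12):
        raise ValueError("recording too short to contain a night")
    min_run = int(round(cfg.min_sleep_run_min * 60.0 / states.epoch_length))

    first_night = times[0].date() - timedelta(days=1)
    last_night = times[-1].date()
    periods: list[SleepPeriod] = []
    night = first_night
    while night <= last_night:
        window = _night_window(states, night, diary, series, cfg)
        night = night + timedelta(days=1)
        if window is None:
            continue
        lo, hi, source = window
        i0 = int(np.searchsorted(times, lo, side="left"))
        i1 = int(np.searchsorted(times, hi, side="right"))
        if i1 - i0 < min_run:
            continue
        seg = states.states[i0:i1]
        starts: list[int] = []
        ends: list[int] = []
        for value, start, length in _runs(seg):
            if value == SLEEP and length >= min_run:
                starts.append(i0 + start)
                ends.append(i0 + start + length - 1)
        if not starts:
            continue
        onset, offset = starts[0], ends[-1]
        periods.append(
            SleepPeriod(
                night_date=night - timedelta(days=1),
                onset=onset,
                offset=offset,
                onset_time=times[onset],
                offset_time=times[offset],
                source=source,
            )
        )
    return periods
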