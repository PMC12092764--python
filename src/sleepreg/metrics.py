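"""Per-night and per-recording sleep metrics derived from scored epochs.

Definitions (per nocturnal sleep period, onset..offset inclusive):

* TST  — total sleep time: minutes scored sleep inside the period.
* WASO — wake after sleep onset: minutes scored wake inside the period.
* Sleep efficiency — 100 * TST / time in bed, where time in bed is the diary
  window when available and the detected period otherwise.
* Fragmentation index — by default, the number of wake bouts inside the
  period per hour of TST. A mobility-based alternative (percent mobile epochs
  plus percent of immobile bouts of at most one minute) is available when raw
  activity counts are supplied; neither definition is normative for binary
  actigraphy states, so both are exposed.
* Average sleep per 24 h — minutes scored sleep (nocturnal plus naps) over
  all full days divided by the number of days.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, time, timedelta

import numpy as np

from .io import ActigraphySeries
from .regularity import DayGrid
from .scoring import SLEEP, WAKE, SleepPeriod, SleepWakeSeries, _runs

__all__ = ["NightMetrics", "compute_night_metrics", "compute_avg_sleep_per_24h",
           "summarise_nights"]


@dataclass
class NightMetrics:
    night_date: object
    tst: float  # minutes
    waso: float  # minutes
    sleep_efficiency: float  # percent of time in bed
    fragmentation_index: float  # wake bouts per hour of TST (default definition)
    time_in_bed: float  # minutes
    n_wake_bouts: int
    fragmentation_index_mobility: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.sleep_efficiency <= 100.0 + 1e-9:
            raise ValueError("sleep efficiency must lie in [0, 100]")
        if self.waso < 0 or self.tst < 0:
            raise ValueError("TST and WASO must be non-negative")


def _diary_minutes(period: SleepPeriod, diary_window) -> float | None:
    if diary_window is None:
        return None
    attempted, wake = diary_window
    night = period.night_date
    nxt = night + timedelta(days=1)
    sleep_dt = datetime.combine(night if attempted >= time(12, 0) else nxt, attempted)
    wake_dt = datetime.combine(nxt, wake)
    dur = (wake_dt - sleep_dt).total_seconds() / 60.0
    return dur if dur > 0 else None


def compute_night_metrics(
    states: SleepWakeSeries,
    period: SleepPeriod,
    diary_window: tuple[time, time] | None = None,
    series: ActigraphySeries | None = None,
    mobility_threshold: int = 2,
) -> NightMetrics:
    """Compute TST, WASO, efficiency and fragmentation for one night.

    ``diary_window`` is the (attempted_sleep, final_wake) clock-time pair for
    the night and, when given, defines time in bed; otherwise the detected
    period duration is used. Passing the raw ``series`` additionally computes
    the mobility-based fragmentation alternative.
    """
    if period.offset <= period.onset:
        raise ValueError("empty sleep period")
    seg = states.states[period.onset : period.offset + 1]
    if seg.size == 0:
        raise ValueError("sleep period outside recording")
    epoch_min = states.epoch_length / 60.0
    tst = float(np.sum(seg == SLEEP) * epoch_min)
    waso = float(np.sum(seg == WAKE) * epoch_min)
    wake_bouts = sum(1 for value, _, _ in _runs(seg) if value == WAKE)

    tib = _diary_minutes(period, diary_window)
    if tib is None:
        tib = seg.size * epoch_min
    efficiency = min(100.0, 100.0 * tst / tib) if tib > 0 else 0.0
    frag = (wake_bouts / (tst / 60.0)) if tst > 0 else 0.0

    frag_mobility = None
    if series is not None:
        counts = series.activity[period.onset : period.offset + 1]
        mobile = counts >= mobility_threshold
        pct_mobile = 100.0 * np.mean(mobile)
        immobile_runs = [r for r in _runs((~mobile).astype(np.int8)) if r[0] == 1]
        one_min = max(1, int(round(60.0 / states.epoch_length)))
        short = sum(1 for _, _, length in immobile_runs if length <= one_min)
        pct_short = 100.0 * short / len(immobile_runs) if immobile_runs else 0.0
        frag_mobility = float(pct_mobile + pct_short)

    return NightMetrics(
        night_date=period.night_date,
        tst=tst,
        waso=waso,
        sleep_efficiency=efficiency,
        fragmentation_index=frag,
        time_in_bed=float(tib),
        n_wake_bouts=int(wake_bouts),
        fragmentation_index_mobility=frag_mobility,
    )


def compute_avg_sleep_per_24h(states: SleepWakeSeries, grid: DayGrid) -> float:
    """Minutes of sleep per 24 h averaged over the full days of the grid,
    counting nocturnal sleep and naps alike."""
    total_sleep = float(np.sum(grid.states == SLEEP))
    return total_sleep * (grid.epoch_length / 60.0) / grid.n_days


def summarise_nights(nights: list[NightMetrics]) -> dict[str, float]:
    """Per-recording means of the nightly metrics."""
    if not nights:
        return {
            "tst_min": np.nan,
            "waso_min": np.nan,
            "sleep_efficiency_pct": np.nan,
            "fragmentation_index": np.nan,
            "n_nights": 0,
        }
    return {
        "tst_min": float(np.mean([n.tst for n in nights])),
        "waso_min": float(np.mean([n.waso for n in nights])),
        "sleep_efficiency_pct": float(np.mean([n.sleep_efficiency for n in nights])),
        "fragmentation_index": float(np.mean([n.fragmentation_index for n in nights])),
        "n_nights": len(nights),
    }
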