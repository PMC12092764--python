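"""Sleep Regularity Index over a day-by-epoch grid.

The SRI measures the probability that an individual is in the same state
(asleep vs awake) at any two clock times 24 h apart, rescaled so that 100 is a
perfectly repeating pattern and 0 the expectation for a completely random one:

    SRI = -100 + 200 / (M (N - 1)) * sum_j sum_i delta(s[i, j], s[i+1, j])

for N days of M daily epochs, where delta is 1 when the state on day i equals
the state on day i+1 at the same epoch j. Epoch pairs with a missing member
are excluded from both the numerator and the denominator (pairwise deletion
with renormalisation); the recording-level validity criteria bound how much
missingness can occur in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .scoring import MISSING, SleepWakeSeries

__all__ = [
    "DayGrid",
    "ValidityCriteria",
    "ValidityReport",
    "SriResult",
    "build_day_grid",
    "screen_validity",
    "compute_sri",
    "classify_regularity",
]

SECONDS_PER_DAY = 86400


@dataclass
class DayGrid:
    """N-day x M-epoch matrix of sleep(1)/wake(0)/missing(-1) states.

    Rows are whole calendar days anchored at local midnight; M * epoch_length
    equals 86400 (M = 2880 at 30-s epochs).
    """

    states: np.ndarray
    start_date: date
    epoch_length: int = 30

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.ndim != 2 or self.states.shape[0] < 1:
            raise ValueError("grid must be a 2-d matrix with N >= 1 rows")
        if self.states.shape[1] * self.epoch_length != SECONDS_PER_DAY:
            raise ValueError("M x epoch_length must equal 86400")

    @property
    def n_days(self) -> int:
        return int(self.states.shape[0])

    @property
    def epochs_per_day(self) -> int:
        return int(self.states.shape[1])

    def dates(self) -> list[date]:
        return [self.start_date + timedelta(days=i) for i in range(self.n_days)]

    @property
    def weekend_days_present(self) -> bool:
        return any(d.weekday() >= 5 for d in self.dates())

    @property
    def missing_hours(self) -> float:
        return float(np.sum(self.states == MISSING) * self.epoch_length / 3600.0)


def build_day_grid(states: SleepWakeSeries) -> DayGrid:
    """Trim a scored series to whole midnight-to-midnight days and grid it.

    Partial leading/trailing days are dropped; an error is raised if fewer
    than one full calendar day remains.
    """
    epoch_len = int(states.epoch_length)
    m = SECONDS_PER_DAY // epoch_len
    start = states.start_time
    midnight = start.normalize()
    if start != midnight:
        midnight = midnight + pd.Timedelta(days=1)
    lead = int((midnight - start).total_seconds()) // epoch_len
    if (midnight - start) != pd.Timedelta(seconds=lead * epoch_len):
        raise ValueError("series start time is not aligned to the epoch grid")
    n_days = (states.n_epochs - lead) // m
    if n_days < 1:
        raise ValueError("insufficient full days (need at least one midnight-to-midnight day)")
    grid = states.states[lead : lead + n_days * m].reshape(n_days, m)
    return DayGrid(states=grid, start_date=midnight.date(), epoch_length=epoch_len)


@dataclass
class ValidityCriteria:
    """Recording-level screening rules for a reliable SRI.

    At least ``min_days`` full wear days, at most ``max_missing_hours`` of no
    recording, and (ideally) a weekend day: the weekend rule is a warning by
    default and an exclusion when ``strict_weekend`` is set.
    """

    min_days: int = 5
    max_missing_hours: float = 2.0
    strict_weekend: bool = False


@dataclass
class ValidityReport:
    n_full_days: int
    has_weekend_day: bool
    total_missing_hours: float
    valid: bool
    reasons: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def screen_validity(grid: DayGrid, criteria: ValidityCriteria | None = None) -> ValidityReport:
    """Screen a day grid against the validity criteria.

    Returns a report with per-criterion outcomes; ``reasons`` lists the failed
    exclusion criteria and ``warnings`` the advisory ones.
    """
    criteria = criteria or ValidityCriteria()
    reasons: list[str] = []
    warnings: list[str] = []
    n = grid.n_days
    if n < criteria.min_days:
        reasons.append(f"fewer than {criteria.min_days} valid wear days")
    missing = grid.missing_hours
    if missing > criteria.max_missing_hours:
        reasons.append(f"> {criteria.max_missing_hours:g} h of no recording")
    weekend = grid.weekend_days_present
    if not weekend:
        msg = "no weekend day in recording"
        if criteria.strict_weekend:
            reasons.append(msg)
        else:
            warnings.append(msg)
    return ValidityReport(
        n_full_days=n,
        has_weekend_day=weekend,
        total_missing_hours=missing,
        valid=not reasons,
        reasons=reasons,
        warnings=warnings,
    )


@dataclass
class SriResult:
    """SRI value with pair accounting and (optional) quintile class."""

    sri: float
    n_pairs_used: int
    n_pairs_missing: int
    regularity_class: str = "unclassified"

    def __post_init__(self) -> None:
        if not -100.0 - 1e-9 <= self.sri <= 100.0 + 1e-9:
            raise ValueError(f"SRI {self.sri} outside [-100, 100]")


def compute_sri(grid: DayGrid) -> SriResult:
    """Evaluate the SRI over all 24-h-apart epoch pairs of the grid.

    Pairs with a missing member are dropped and the denominator renormalised;
    an error is raised when no usable pair remains (requires N >= 2).
    """
    s = grid.states
    if grid.n_days < 2:
        raise ValueError("SRI needs at least two full days")
    a, b = s[:-1], s[1:]
    usable = (a != MISSING) & (b != MISSING)
    n_total = a.size
    n_used = int(np.sum(usable))
    if n_used == 0:
        raise ValueError("no usable 24-h-apart epoch pairs (all missing)")
    agree = int(np.sum((a == b) & usable))
    sri = -100.0 + 200.0 * agree / n_used
    return SriResult(sri=sri, n_pairs_used=n_used, n_pairs_missing=n_total - n_used)


def classify_regularity(cohort_sris) -> list[str]:
    """Assign Regular/Irregular classes by cohort quintile.

    The bottom quintile is 'irregular', the top quintile 'regular', the rest
    'normal'. Quintile cuts use midpoint interpolation of the empirical
    quantile; values exactly at a cut go to the extreme class. Cohorts of
    fewer than five values (or with degenerate, all-equal quintiles) carry no
    ordering information and are returned 'unclassified' / 'normal'
    respectively.
    """
    sris = np.asarray(list(cohort_sris), dtype=float)
    if sris.size < 5:
        return ["unclassified"] * sris.size
    q20, q80 = np.quantile(sris, [0.2, 0.8], method="midpoint")
    if q20 == q80:
        return ["normal"] * sris.size
    out = []
    for v in sris:
        if v <= q20:
            out.append("irregular")
        elif v >= q80:
            out.append("regular")
        else:
            out.append("normal")
    return out
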