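"""Synthetic actigraphy cohorts with known ground truth.

The generator is a clock-gated two-state process, not a physiological
circadian model: each participant has a habitual nocturnal sleep window whose
nightly onset and offset are jittered independently with a participant-
specific standard deviation, plus Poisson daytime naps, optional non-wear
gaps, and activity counts drawn from a zero-inflated low-mean distribution in
sleep and a right-skewed gamma in wake. That is sufficient to produce the
statistical structure the downstream analysis assumes while keeping every
quantity controllable.

Known linear effects on regularity (group, age, sex) are injected through the
jitter channel. For independent Gaussian boundary jitter with SD sigma
(minutes), the expected state disagreement between adjacent days is
``4 * sigma / sqrt(pi)`` minutes per day pair (two boundaries, each
contributing ``E|N(0, 2 sigma^2)|``), so the expected SRI falls linearly with
sigma at ``K_JITTER ~= 0.3134`` SRI units per minute. Inverting this map turns
a target linear predictor on the SRI scale into a per-participant sigma; naps
subtract a further ``(200/1440) * 2 * E[nap minutes per day]`` SRI units on
average. The realized injected-to-measured mapping is additionally calibrated
empirically in the test suite, since the analytic map ignores rare boundary
overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ActigraphySeries,
    ParticipantRecord,
    SleepDiary,
    write_cohort_metadata,
    write_epoch_csv,
    write_sleep_diary,
)
from .regularity import DayGrid, compute_sri

__all__ = [
    "K_JITTER",
    "SimulationSpec",
    "GroundTruth",
    "CohortSim",
    "simulate_truth",
    "simulate_participant",
    "simulate_cohort",
    "simulate_covariates",
    "simulate_sri_cohort",
]

MIN_PER_DAY = 1440

# expected SRI units lost per minute of boundary-jitter SD:
# 200/1440 * 4 / sqrt(pi)
K_JITTER = 200.0 * 4.0 / (np.sqrt(np.pi) * MIN_PER_DAY)

# expected SRI units lost per expected minute of daily napping: 200/1440 * 2
K_NAP = 200.0 * 2.0 / MIN_PER_DAY


@dataclass
class SimulationSpec:
    """Generator settings; defaults reproduce the study conditions.

    Cohort sizes default to 162 stroke / 60 control participants wearing the
    device for 7 days of 30-s epochs. ``group_effect``, ``age_effect`` (per
    year, centred at age 60) and ``sex_effect`` (female vs male) are target
    linear effects on the SRI scale with the directions observed in stroke
    cohorts (stroke and older age lower the SRI, female sex raises it);
    ``sri_noise_sd`` is between-participant regularity heterogeneity beyond
    the covariates. ``regularity_sigma`` is the nightly onset/offset jitter SD
    (minutes) at the reference covariates (control, male, age 60); it anchors
    the cohort mean SRI in the mid-40s together with the nap load.
    """

    n_stroke: int = 162
    n_control: int = 60
    n_days: int = 7
    epoch_length: int = 30
    start_date: date = date(2024, 1, 1)  # a Monday: weekend on days 6-7

    # regularity model
    regularity_sigma: float = 120.0  # minutes, at reference covariates
    group_effect: float = -6.0
    age_effect: float = -0.12
    sex_effect: float = 5.0
    sri_noise_sd: float = 9.0
    frag_wake_prob: float = 0.0  # iid within-sleep wake flips (stress knob)
    degenerate_random_sleep: bool = False  # iid Bernoulli(0.5) states

    # habitual schedule
    mean_onset_minutes: float = 23 * 60.0  # clock minutes of habitual onset
    onset_between_sd: float = 45.0  # between-participant onset spread
    mean_sleep_duration: float = 480.0
    duration_between_sd: float = 25.0

    # naps
    nap_rate: float = 1.2  # expected naps/day
    nap_duration: float = 70.0  # mean minutes
    nap_window: tuple[float, float] = (10 * 60.0, 18 * 60.0)  # clock minutes

    # non-wear
    nonwear_rate: float = 0.5  # expected gaps per recording
    nonwear_duration: float = 20.0  # mean minutes

    # activity-count emission
    sleep_zero_prob: float = 0.85
    sleep_count_mean: float = 2.0
    wake_count_mean: float = 180.0
    wake_count_shape: float = 1.6

    # diary and markers
    diary_noise_sd: float = 10.0  # minutes of reporting noise
    marker_compliance: float = 0.85

    # questionnaire generation (latent link is the SRI-scale predictor)
    sci_center: float = 16.0
    sci_slope: float = 0.12
    sci_sd: float = 4.5
    sci_present_prob: float = 0.95
    phq8_center: float = 8.8
    phq8_slope: float = -0.155
    phq8_sd: float = 5.2
    phq8_present_prob: float = 0.72
    sfsis_center: float = 26.7
    sfsis_slope: float = 0.24
    sfsis_sd: float = 5.0
    sfsis_present_prob: float = 0.38
    mrs_mean: float = 2.28
    mrs_sd: float = 1.0
    mrs_present_prob: float = 0.33

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("nap_rate", "nonwear_rate", "regularity_sigma",
                     "sri_noise_sd", "diary_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        for name in ("sleep_zero_prob", "marker_compliance", "frag_wake_prob",
                     "sci_present_prob", "phq8_present_prob",
                     "sfsis_present_prob", "mrs_present_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def epochs_per_day(self) -> int:
        return 86400 // self.epoch_length

    @property
    def epochs_per_minute(self) -> float:
        return 60.0 / self.epoch_length

    @property
    def reference_sri(self) -> float:
        """Expected SRI at the reference covariates under the analytic map."""
        nap_minutes = self.nap_rate * self.nap_duration
        return 100.0 - K_JITTER * self.regularity_sigma - K_NAP * nap_minutes

    def linear_predictor(self, record: ParticipantRecord) -> float:
        """Target expected SRI for a participant (before heterogeneity)."""
        return (
            self.reference_sri
            + self.group_effect * record.group
            + self.age_effect * (record.age - 60.0)
            + self.sex_effect * (1.0 if record.is_female else 0.0)
        )

    def sigma_for(self, target_sri: float) -> float:
        """Invert the analytic jitter map for a target expected SRI.

        A zero baseline (``regularity_sigma == 0``) disables jitter entirely:
        the cohort is perfectly regular and covariate effects have no channel.
        """
        if self.regularity_sigma == 0:
            return 0.0
        sigma = self.regularity_sigma + (self.reference_sri - target_sri) / K_JITTER
        return float(np.clip(sigma, 0.0, 400.0))


@dataclass
class GroundTruth:
    """Everything the generator knows about one simulated participant."""

    participant_id: str
    grid: np.ndarray  # n_days x epochs_per_day, 1 sleep / 0 wake
    onsets: np.ndarray  # absolute minutes from day-0 midnight, per night
    offsets: np.ndarray
    naps: list[tuple[float, float]]  # (start_abs_min, duration_min)
    nonwear: np.ndarray  # bool per epoch, injected gaps
    linear_predictor: float
    latent_sri: float  # linear predictor + participant heterogeneity
    sigma: float
    true_sri: float = field(default=np.nan)

    def sleep_fraction_per_night(self) -> np.ndarray:
        """Fraction of each diary window truly spent asleep (clipped to the
        recording)."""
        n_epochs = self.grid.size
        epm = n_epochs / (len(self.grid) * MIN_PER_DAY)
        flat = self.grid.reshape(-1)
        out = []
        for on, off in zip(self.onsets, self.offsets):
            i0 = int(np.clip(round(on * epm), 0, n_epochs))
            i1 = int(np.clip(round(off * epm), 0, n_epochs))
            if i1 <= i0:
                out.append(np.nan)
            else:
                out.append(float(np.mean(flat[i0:i1] == 1)))
        return np.asarray(out)


def _truth_grid_and_nights(
    spec: SimulationSpec, sigma: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[tuple[float, float]]]:
    m = spec.epochs_per_day
    n_epochs = spec.n_days * m
    epm = spec.epochs_per_minute
    flat = np.zeros(n_epochs, dtype=np.int8)

    if spec.degenerate_random_sleep:
        flat[:] = rng.integers(0, 2, size=n_epochs)
        nights = np.arange(-1, spec.n_days)
        return flat.reshape(spec.n_days, m), np.full(nights.size, np.nan), np.full(
            nights.size, np.nan
        ), []

    onset_clock = spec.mean_onset_minutes + rng.normal(0.0, spec.onset_between_sd)
    duration = float(
        np.clip(
            spec.mean_sleep_duration + rng.normal(0.0, spec.duration_between_sd),
            300.0,
            660.0,
        )
    )
    # nights -1 .. n_days-1 so every recorded day has a morning and an
    # evening sleep segment (a perfectly regular pattern scores SRI = 100)
    nights = np.arange(-1, spec.n_days)
    onsets = nights * MIN_PER_DAY + onset_clock + rng.normal(0.0, sigma, nights.size)
    offsets = (
        nights * MIN_PER_DAY + onset_clock + duration + rng.normal(0.0, sigma, nights.size)
    )
    offsets = np.maximum(offsets, onsets + 30.0)

    for on, off in zip(onsets, offsets):
        i0 = int(np.clip(round(on * epm), 0, n_epochs))
        i1 = int(np.clip(round(off * epm), 0, n_epochs))
        if i1 > i0:
            flat[i0:i1] = 1

    naps: list[tuple[float, float]] = []
    lo, hi = spec.nap_window
    if spec.nap_rate > 0:
        for day in range(spec.n_days):
            for _ in range(rng.poisson(spec.nap_rate)):
                start = day * MIN_PER_DAY + rng.uniform(lo, hi)
                dur = float(np.clip(rng.exponential(spec.nap_duration), 10.0, 240.0))
                naps.append((start, dur))
                i0 = int(np.clip(round(start * epm), 0, n_epochs))
                i1 = int(np.clip(round((start + dur) * epm), 0, n_epochs))
                flat[i0:i1] = 1

    if spec.frag_wake_prob > 0:
        sleep_idx = np.flatnonzero(flat == 1)
        flip = rng.random(sleep_idx.size) < spec.frag_wake_prob
        flat[sleep_idx[flip]] = 0

    return flat.reshape(spec.n_days, m), onsets, offsets, naps


def simulate_truth(
    spec: SimulationSpec, record: ParticipantRecord, rng: np.random.Generator
) -> GroundTruth:
    """Draw the latent regularity and the true sleep/wake grid (no counts)."""
    lp = spec.linear_predictor(record)
    latent = lp + rng.normal(0.0, spec.sri_noise_sd)
    sigma = spec.sigma_for(latent)
    grid, onsets, offsets, naps = _truth_grid_and_nights(spec, sigma, rng)

    nonwear = np.zeros(grid.size, dtype=bool)
    if spec.nonwear_rate > 0:
        epm = spec.epochs_per_minute
        for _ in range(rng.poisson(spec.nonwear_rate)):
            dur = float(np.clip(rng.exponential(spec.nonwear_duration), 5.0, 600.0))
            start = rng.uniform(0.0, spec.n_days * MIN_PER_DAY - dur)
            i0 = int(round(start * epm))
            i1 = int(round((start + dur) * epm))
            nonwear[i0:i1] = True

    truth = GroundTruth(
        participant_id=record.participant_id,
        grid=grid,
        onsets=onsets,
        offsets=offsets,
        naps=naps,
        nonwear=nonwear,
        linear_predictor=lp,
        latent_sri=latent,
        sigma=sigma,
    )
    day_grid = DayGrid(
        states=grid.copy(), start_date=spec.start_date, epoch_length=spec.epoch_length
    )
    truth.true_sri = compute_sri(day_grid).sri if spec.n_days >= 2 else np.nan
    return truth


def _emit_activity(
    spec: SimulationSpec, flat_states: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    n = flat_states.size
    sleep = flat_states == 1
    counts = np.zeros(n, dtype=np.int64)
    n_sleep = int(sleep.sum())
    if n_sleep:
        nonzero = rng.random(n_sleep) >= spec.sleep_zero_prob
        draws = rng.poisson(spec.sleep_count_mean, n_sleep)
        counts[sleep] = np.where(nonzero, draws, 0)
    n_wake = n - n_sleep
    if n_wake:
        shape = spec.wake_count_shape
        scale = spec.wake_count_mean / shape
        counts[~sleep] = np.round(rng.gamma(shape, scale, n_wake)).astype(np.int64)
    return counts


def simulate_participant(
    spec: SimulationSpec,
    record: ParticipantRecord,
    rng: np.random.Generator,
) -> tuple[ActigraphySeries, SleepDiary, GroundTruth]:
    """Simulate one participant's recording, diary and ground truth.

    The emitted activity series is aligned epoch-for-epoch with the truth
    grid; injected non-wear gaps appear as ``wear=False`` with zero counts;
    event markers are placed at the true (jittered) onsets/offsets with the
    configured compliance probability; diary rows are the true times plus
    reporting noise, rounded to the minute.
    """
    truth = simulate_truth(spec, record, rng)
    flat = truth.grid.reshape(-1)
    counts = _emit_activity(spec, flat, rng)
    counts[truth.nonwear] = 0
    wear = ~truth.nonwear
    epm = spec.epochs_per_minute
    n_epochs = flat.size

    marker = np.zeros(n_epochs, dtype=bool)
    diary_rows = []
    for night, on, off in zip(range(-1, spec.n_days), truth.onsets, truth.offsets):
        if not np.isfinite(on):
            continue
        for t_min in (on, off):
            if rng.random() < spec.marker_compliance:
                idx = int(round((t_min + rng.normal(0.0, 2.0)) * epm))
                if 0 <= idx < n_epochs:
                    marker[idx] = True
        if night < 0:
            continue  # the pre-recording night has no diary row
        rep_on = on + rng.normal(0.0, spec.diary_noise_sd)
        rep_off = off + rng.normal(0.0, spec.diary_noise_sd)
        diary_rows.append(
            {
                "date": spec.start_date + timedelta(days=night),
                "attempted_sleep": _clock_time(rep_on),
                "final_wake": _clock_time(rep_off),
            }
        )

    series = ActigraphySeries(
        participant_id=record.participant_id,
        start_time=pd.Timestamp(datetime.combine(spec.start_date, time(0, 0))),
        activity=counts,
        epoch_length=spec.epoch_length,
        light=None,
        event_marker=marker,
        wear=wear,
    )
    diary = SleepDiary(
        participant_id=record.participant_id,
        nights=pd.DataFrame(diary_rows, columns=["date", "attempted_sleep", "final_wake"]),
    )
    return series, diary, truth


def _clock_time(abs_minutes: float) -> time:
    m = int(round(abs_minutes)) % MIN_PER_DAY
    return time(m // 60, m % 60)


def simulate_covariates(spec: SimulationSpec, rng: np.random.Generator) -> list[ParticipantRecord]:
    """Draw cohort covariates resembling a stroke-vs-control study:
    ages about 61±14 (stroke, range 20-89) and 57±17 (control, range 19-83),
    about 46% female in both arms."""
    records = []
    for i in range(spec.n_stroke + spec.n_control):
        stroke = i < spec.n_stroke
        if stroke:
            age = float(np.clip(rng.normal(61.0, 14.0), 20.0, 89.0))
        else:
            age = float(np.clip(rng.normal(57.0, 17.0), 19.0, 83.0))
        records.append(
            ParticipantRecord(
                participant_id=f"{'S' if stroke else 'C'}{i + 1:04d}",
                group=1 if stroke else 0,
                age=age,
                sex="female" if rng.random() < 0.46 else "male",
                time_since_stroke=(
                    float(np.clip(abs(rng.normal(5.0, 5.0)), 0.1, 31.0)) if stroke else None
                ),
            )
        )
    return records


def _attach_questionnaires(
    spec: SimulationSpec,
    records: list[ParticipantRecord],
    latents: np.ndarray,
    rng: np.random.Generator,
) -> None:
    center = spec.reference_sri
    for rec, latent in zip(records, latents):
        dev = latent - center
        if rng.random() < spec.sci_present_prob:
            rec.sci = float(
                np.clip(round(spec.sci_center + spec.sci_slope * dev
                              + rng.normal(0.0, spec.sci_sd)), 0, 32)
            )
        if rec.group == 1:
            if rng.random() < spec.phq8_present_prob:
                rec.phq8 = float(
                    np.clip(round(spec.phq8_center + spec.phq8_slope * dev
                                  + rng.normal(0.0, spec.phq8_sd)), 0, 24)
                )
            if rng.random() < spec.mrs_present_prob:
                rec.mrs = float(np.clip(round(rng.normal(spec.mrs_mean, spec.mrs_sd)), 0, 6))
            if rng.random() < spec.sfsis_present_prob:
                rec.sfsis = float(
                    np.clip(spec.sfsis_center + spec.sfsis_slope * dev
                            + rng.normal(0.0, spec.sfsis_sd), 0.0, 100.0)
                )


@dataclass
class CohortSim:
    """A simulated cohort: records, per-participant data and the truth table."""

    spec: SimulationSpec
    records: list[ParticipantRecord]
    participants: list[tuple[ActigraphySeries, SleepDiary, GroundTruth]]
    ground_truth: pd.DataFrame


def simulate_cohort(spec: SimulationSpec, out_dir: str | Path | None = None) -> CohortSim:
    """Simulate a full cohort; optionally write it to disk as CSV files.

    Deterministic under ``spec.seed`` (per-participant RNG streams are spawned
    hierarchically, so results do not depend on iteration order). When
    ``out_dir`` is given, writes ``epochs/<id>.csv``, ``diaries/<id>.csv``,
    ``metadata.csv`` and ``ground_truth.csv``.
    """
    root = np.random.SeedSequence(spec.seed)
    cov_ss, q_ss, *part_ss = root.spawn(2 + spec.n_stroke + spec.n_control)
    records = simulate_covariates(spec, np.random.default_rng(cov_ss))

    participants = []
    rows = []
    for rec, ss in zip(records, part_ss):
        series, diary, truth = simulate_participant(spec, rec, np.random.default_rng(ss))
        participants.append((series, diary, truth))
        rows.append(
            {
                "participant_id": rec.participant_id,
                "group": rec.group,
                "age": rec.age,
                "sex_female": int(rec.is_female),
                "linear_predictor": truth.linear_predictor,
                "latent_sri": truth.latent_sri,
                "sigma": truth.sigma,
                "true_sri": truth.true_sri,
            }
        )
    latents = np.array([r["latent_sri"] for r in rows])
    _attach_questionnaires(spec, records, latents, np.random.default_rng(q_ss))
    truth_df = pd.DataFrame(rows)

    if out_dir is not None:
        out = Path(out_dir)
        (out / "epochs").mkdir(parents=True, exist_ok=True)
        (out / "diaries").mkdir(parents=True, exist_ok=True)
        for (series, diary, _), rec in zip(participants, records):
            write_epoch_csv(series, out / "epochs" / f"{rec.participant_id}.csv")
            write_sleep_diary(diary, out / "diaries" / f"{rec.participant_id}.csv")
        write_cohort_metadata(records, out / "metadata.csv")
        truth_df.to_csv(out / "ground_truth.csv", index=False)

    return CohortSim(spec=spec, records=records, participants=participants,
                     ground_truth=truth_df)


def simulate_sri_cohort(spec: SimulationSpec, seed: int | None = None) -> pd.DataFrame:
    """Fast path for statistical calibration: covariates plus the SRI of the
    ground-truth sleep/wake grid, skipping count emission and scoring.

    Used for parameter-recovery and type-I-error studies where the quantity
    under test is the cohort-statistics stage.
    """
    if seed is not None:
        spec = dataclass_replace(spec, seed=seed)
    root = np.random.SeedSequence(spec.seed)
    cov_ss, _, *part_ss = root.spawn(2 + spec.n_stroke + spec.n_control)
    records = simulate_covariates(spec, np.random.default_rng(cov_ss))
    rows = []
    for rec, ss in zip(records, part_ss):
        truth = simulate_truth(spec, rec, np.random.default_rng(ss))
        rows.append(
            {
                "participant_id": rec.participant_id,
                "group": rec.group,
                "age": rec.age,
                "sex_female": int(rec.is_female),
                "sri": truth.true_sri,
                "linear_predictor": truth.linear_predictor,
            }
        )
    return pd.DataFrame(rows)


def dataclass_replace(spec: SimulationSpec, **kwargs) -> SimulationSpec:
    from dataclasses import replace

    return replace(spec, **kwargs)
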