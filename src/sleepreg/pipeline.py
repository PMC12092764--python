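"""End-to-end orchestration: counts -> states -> SRI -> metrics -> statistics.

`process_participant` takes one recording (plus optional diary) through
non-wear detection, activity scoring, Webster rescoring, day-gridding,
validity screening, SRI computation and night metrics. `run_cohort` applies
it across participants, logs inclusion/exclusion decisions and assigns
regularity quintile classes within the included sample. `analyze_cohort`
reproduces the cohort statistics stage on the joined results table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ActigraphySeries, SleepDiary
from .metrics import compute_avg_sleep_per_24h, compute_night_metrics, summarise_nights
from .regularity import (
    ValidityCriteria,
    ValidityReport,
    build_day_grid,
    classify_regularity,
    compute_sri,
    screen_validity,
)
from .scoring import (
    PeriodConfig,
    ScoringConfig,
    apply_webster_rescoring,
    delimit_sleep_periods,
    detect_nonwear,
    score_ucsd,
)
from . import stats as cstats

logger = logging.getLogger("sleepreg")

__all__ = ["PipelineConfig", "ParticipantResult", "CohortAnalysis",
           "process_participant", "run_cohort", "analyze_cohort"]

SLEEP_METRICS = (
    "tst_min",
    "waso_min",
    "fragmentation_index",
    "sleep_efficiency_pct",
    "sci",
)


@dataclass
class PipelineConfig:
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    period: PeriodConfig = field(default_factory=PeriodConfig)
    validity: ValidityCriteria = field(default_factory=ValidityCriteria)
    nonwear_min_zero_run: float = 90.0
    webster: bool = True


@dataclass
class ParticipantResult:
    participant_id: str
    sri: float
    n_pairs_used: int
    validity: ValidityReport
    night_summary: dict
    avg_sleep_per_24h: float
    n_periods: int

    def to_row(self) -> dict:
        row = {
            "participant_id": self.participant_id,
            "sri": self.sri,
            "n_days": self.validity.n_full_days,
            "valid": self.validity.valid,
            "exclusion_reasons": "; ".join(self.validity.reasons),
            "avg_sleep_per_24h_min": self.avg_sleep_per_24h,
            "n_periods": self.n_periods,
        }
        row.update(
            {k: v for k, v in self.night_summary.items() if k != "n_nights"}
        )
        row["n_nights"] = self.night_summary.get("n_nights", 0)
        return row


def process_participant(
    series: ActigraphySeries,
    diary: SleepDiary | None = None,
    cfg: PipelineConfig | None = None,
) -> ParticipantResult:
    """Run the whole per-participant pipeline on one recording."""
    cfg = cfg or PipelineConfig()
    series = detect_nonwear(series, cfg.nonwear_min_zero_run)
    scored = score_ucsd(series, cfg.scoring)
    if cfg.webster:
        scored = apply_webster_rescoring(scored, cfg.scoring)
    grid = build_day_grid(scored)
    report = screen_validity(grid, cfg.validity)
    sri_result = compute_sri(grid) if grid.n_days >= 2 else None
    sri = sri_result.sri if sri_result is not None else float("nan")

    periods = delimit_sleep_periods(scored, diary, series, cfg.period)
    nights = []
    for period in periods:
        window = diary.window_for(period.night_date) if diary is not None else None
        nights.append(compute_night_metrics(scored, period, window, series))
    summary = summarise_nights(nights)
    avg24 = compute_avg_sleep_per_24h(scored, grid)

    result = ParticipantResult(
        participant_id=series.participant_id,
        sri=sri,
        n_pairs_used=sri_result.n_pairs_used if sri_result is not None else 0,
        validity=report,
        night_summary=summary,
        avg_sleep_per_24h=avg24,
        n_periods=len(periods),
    )
    if report.valid:
        logger.info("included %s (SRI %.2f, %d days)", series.participant_id, sri,
                    report.n_full_days)
    else:
        logger.info("excluded %s: %s", series.participant_id,
                    "; ".join(report.reasons))
    return result


def run_cohort(
    participants: list[tuple[ActigraphySeries, SleepDiary | None]],
    cfg: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Process every participant; returns (results, exclusion log).

    Regularity quintile classes are assigned within the included sample only.
    """
    cfg = cfg or PipelineConfig()
    rows = []
    exclusions = []
    for series, diary in participants:
        try:
            result = process_participant(series, diary, cfg)
        except ValueError as exc:
            exclusions.append(
                {"participant_id": series.participant_id, "reasons": str(exc)}
            )
            continue
        rows.append(result.to_row())
        if not result.validity.valid:
            exclusions.append(
                {
                    "participant_id": series.participant_id,
                    "reasons": "; ".join(result.validity.reasons),
                }
            )
    results = pd.DataFrame(rows)
    if not results.empty:
        included = results["valid"].to_numpy(dtype=bool)
        classes = np.array(["unclassified"] * len(results), dtype=object)
        if included.sum() >= 5:
            classes[included] = classify_regularity(results.loc[included, "sri"])
        results["regularity_class"] = classes
    return results, pd.DataFrame(exclusions, columns=["participant_id", "reasons"])


@dataclass
class CohortAnalysis:
    """Bundle of the cohort-level statistical outputs."""

    demographics: dict
    ols: cstats.OlsFit
    ols_with_sci: cstats.OlsFit | None
    correlations: pd.DataFrame
    fisher: pd.DataFrame
    permutation: cstats.PermutationSummary | None
    power: cstats.PowerSpec
    interaction_diagnostic: dict


def _group_correlations(
    df: pd.DataFrame, metrics: tuple[str, ...], alpha_adj: float
) -> list[dict]:
    rows = []
    for group, sub in df.groupby("group"):
        for metric in metrics:
            if metric not in sub.columns:
                continue
            data = sub[["sri", metric, "age", "sex_female"]].dropna()
            if len(data) < 10:
                continue
            pc = cstats.partial_pearson(
                data["sri"], data[metric], data[["age", "sex_female"]],
                alpha_adjusted=alpha_adj,
            )
            rows.append(
                {
                    "group": group,
                    "metric": metric,
                    "r": pc.r,
                    "p": pc.p,
                    "n": pc.n,
                    "alpha_adjusted": alpha_adj,
                    "significant": pc.significant,
                    "strength": cstats.label_correlation_strength(pc.r)
                    if np.isfinite(pc.r)
                    else "",
                }
            )
    return rows


def analyze_cohort(
    cohort: pd.DataFrame,
    n_perm: int = 500,
    seed: int = 0,
    alpha_family: float = 0.05,
) -> CohortAnalysis:
    """Cohort statistics on a joined results+metadata table.

    Expects columns ``sri``, ``group`` (0/1), ``age``, ``sex_female`` and
    optionally the sleep metrics and questionnaires. Only participants with a
    finite SRI enter; questionnaire analyses are complete-case.
    """
    df = cohort[np.isfinite(cohort["sri"])].reset_index(drop=True)
    stroke = df[df["group"] == 1]
    control = df[df["group"] == 0]

    t, dof, p_age = cstats.welch_t(stroke["age"], control["age"])
    sex_table = np.array(
        [
            [int((stroke["sex_female"] == 1).sum()), int((stroke["sex_female"] == 0).sum())],
            [int((control["sex_female"] == 1).sum()), int((control["sex_female"] == 0).sum())],
        ]
    )
    chi2, p_sex = cstats.chi_square_2x2(sex_table)
    demographics = {
        "n_stroke": len(stroke),
        "n_control": len(control),
        "sri_mean_stroke": float(stroke["sri"].mean()),
        "sri_sd_stroke": float(stroke["sri"].std(ddof=1)),
        "sri_mean_control": float(control["sri"].mean()),
        "sri_sd_control": float(control["sri"].std(ddof=1)),
        "age_welch_t": t,
        "age_welch_df": dof,
        "age_welch_p": p_age,
        "sex_chi2": chi2,
        "sex_chi2_p": p_sex,
    }

    ols = cstats.fit_ols(df["sri"], df[["group", "age", "sex_female"]])

    ols_sci = None
    if "sci" in df.columns:
        cc = df[["sri", "group", "age", "sex_female", "sci"]].dropna()
        if len(cc) > 10:
            ols_sci = cstats.fit_ols(cc["sri"], cc[["group", "age", "sex_female", "sci"]])

    alpha_adj = cstats.bonferroni(alpha_family, len(SLEEP_METRICS))
    corr_rows = _group_correlations(df, SLEEP_METRICS + ("avg_sleep_per_24h_min",), alpha_adj)
    for metric in ("phq8", "sfsis", "mrs", "time_since_stroke"):
        if metric in stroke.columns:
            data = stroke[["sri", metric, "age", "sex_female"]].dropna()
            if len(data) >= 10:
                pc = cstats.partial_pearson(
                    data["sri"], data[metric], data[["age", "sex_female"]],
                    alpha_adjusted=alpha_family,
                )
                corr_rows.append(
                    {
                        "group": 1,
                        "metric": metric,
                        "r": pc.r,
                        "p": pc.p,
                        "n": pc.n,
                        "alpha_adjusted": alpha_family,
                        "significant": pc.significant,
                        "strength": cstats.label_correlation_strength(pc.r),
                    }
                )
    correlations = pd.DataFrame(corr_rows)

    fisher_rows = []
    if not correlations.empty:
        both = correlations[correlations["metric"].isin(SLEEP_METRICS + ("avg_sleep_per_24h_min",))]
        for metric, sub in both.groupby("metric"):
            if set(sub["group"]) == {0, 1}:
                r1 = sub[sub["group"] == 1].iloc[0]
                r0 = sub[sub["group"] == 0].iloc[0]
                try:
                    fz = cstats.fisher_r_to_z(r1["r"], int(r1["n"]), r0["r"], int(r0["n"]))
                except ValueError:
                    continue
                fisher_rows.append({"metric": metric, "z": fz.z, "p": fz.p})
    fisher = pd.DataFrame(fisher_rows, columns=["metric", "z", "p"])

    permutation = None
    if len(stroke) > len(control) >= 10:
        permutation = cstats.permutation_subsample_test(
            df, n_subsample=len(control), n_perm=n_perm, seed=seed
        )

    power = cstats.sensitivity_power_ancova(
        alpha=0.05, power=0.80, total_n=len(df), n_groups=2, n_covariates=2
    )
    interaction = cstats.ancova_interaction_diagnostic(df)

    return CohortAnalysis(
        demographics=demographics,
        ols=ols,
        ols_with_sci=ols_sci,
        correlations=correlations,
        fisher=fisher,
        permutation=permutation,
        power=power,
        interaction_diagnostic=interaction,
    )
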