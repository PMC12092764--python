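"""Cohort-level statistics for sleep-regularity analyses.

Covers the statistical stage of a two-group actigraphy study: Welch's t and
chi-square demographics tests, an OLS model predicting SRI from group, age and
sex (Wald-t inference, 95% CIs, standardized betas), covariate-adjusted
(partial) Pearson correlations with Bonferroni control, Fisher r-to-z
comparison of correlations between independent groups, permutation
subsampling of the larger group, and a noncentral-F sensitivity power
analysis for an ANCOVA-style design (solve for the smallest detectable
Cohen's f given alpha, power and N).

Standard machinery (distributions, OLS fitting) comes from scipy and
statsmodels; the result surfaces here are small typed containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

__all__ = [
    "OlsFit",
    "PartialCorr",
    "FisherZComparison",
    "PowerSpec",
    "PermutationSummary",
    "welch_t",
    "chi_square_2x2",
    "fit_ols",
    "partial_pearson",
    "bonferroni",
    "fisher_r_to_z",
    "permutation_subsample_test",
    "sensitivity_power_ancova",
    "label_correlation_strength",
    "ancova_interaction_diagnostic",
    "residual_normality_diagnostic",
]


# ---------------------------------------------------------------------------
# simple two-sample tests


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch two-sample t-test (unequal variances).

    Returns ``(t, df, p)`` with Welch–Satterthwaite degrees of freedom and a
    two-sided p-value. Degenerate samples (zero variance in both groups with
    equal means) yield ``(nan, nan, nan)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("samples must be finite")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return float("nan"), float("nan"), float("nan")
        raise ValueError("zero variance in both samples with unequal means")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def chi_square_2x2(table, continuity: bool = True) -> tuple[float, float]:
    """Pearson chi-square for a 2x2 table, Yates-corrected by default."""
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("counts must be non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("table has a zero margin")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=continuity)
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# OLS with standardized betas


@dataclass
class OlsFit:
    """OLS fit summary: estimates, Wald-t inference and standardized betas."""

    params: pd.Series
    conf_int: pd.DataFrame  # columns 'lower', 'upper'
    tvalues: pd.Series
    pvalues: pd.Series
    r_squared: float
    r_squared_adj: float
    std_params: pd.Series
    std_conf_int: pd.DataFrame
    df_resid: float
    f_statistic: float
    f_pvalue: float
    nobs: int

    def __post_init__(self) -> None:
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise ValueError("R^2 outside [0, 1]")


def _is_binary(col: pd.Series) -> bool:
    vals = pd.unique(col.dropna())
    return len(vals) <= 2


def fit_ols(response, design: pd.DataFrame) -> OlsFit:
    """Fit ``response ~ intercept + design`` by OLS.

    Inference is Wald-t with 95% CIs. Standardized betas come from refitting
    with the response and all non-binary predictors z-scored; binary (0/1)
    predictors are left on their original scale, so their standardized beta is
    the group contrast on the z-scored response.

    Raises ``ValueError`` naming the collinear columns when the design (with
    intercept) is rank deficient.
    """
    y = np.asarray(response, dtype=float)
    X = pd.DataFrame(design).astype(float).copy()
    if len(X) != y.size:
        raise ValueError("response and design have different lengths")
    if len(X) <= X.shape[1] + 1:
        raise ValueError("need n > number of parameters")
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        collinear = []
        kept: list[str] = []
        for col in Xc.columns:
            trial = Xc[kept + [col]].to_numpy()
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(col)
            else:
                collinear.append(col)
        raise ValueError(f"design is rank deficient; collinear columns: {collinear}")

    fit = sm.OLS(y, Xc).fit()
    ci = fit.conf_int(alpha=0.05)
    ci.columns = ["lower", "upper"]

    Xz = X.copy()
    for col in X.columns:
        if not _is_binary(X[col]):
            sd = X[col].std(ddof=1)
            Xz[col] = (X[col] - X[col].mean()) / sd if sd > 0 else 0.0
    ysd = y.std(ddof=1)
    yz = (y - y.mean()) / ysd if ysd > 0 else np.zeros_like(y)
    zfit = sm.OLS(yz, sm.add_constant(Xz, has_constant="add")).fit()
    zci = zfit.conf_int(alpha=0.05)
    zci.columns = ["lower", "upper"]

    return OlsFit(
        params=fit.params,
        conf_int=ci,
        tvalues=fit.tvalues,
        pvalues=fit.pvalues,
        r_squared=float(fit.rsquared),
        r_squared_adj=float(fit.rsquared_adj),
        std_params=zfit.params,
        std_conf_int=zci,
        df_resid=float(fit.df_resid),
        f_statistic=float(fit.fvalue),
        f_pvalue=float(fit.f_pvalue),
        nobs=int(fit.nobs),
    )


# ---------------------------------------------------------------------------
# partial correlation


@dataclass
class PartialCorr:
    r: float
    p: float
    n: int
    covariates: list[str] = field(default_factory=list)
    alpha_adjusted: float | None = None
    significant: bool | None = None

    def __post_init__(self) -> None:
        if np.isfinite(self.r) and abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| must be <= 1")


def partial_pearson(
    x,
    y,
    covariates: pd.DataFrame | None = None,
    alpha_adjusted: float | None = None,
) -> PartialCorr:
    """Pearson correlation of x and y adjusted for covariates.

    Both variables are regressed on ``[intercept + covariates]`` and the
    residuals correlated; the p-value uses a t distribution with
    ``n - k - 2`` degrees of freedom (k covariates). With no covariates this
    reduces to the plain Pearson correlation. When ``alpha_adjusted`` is
    given (e.g. from :func:`bonferroni`) the result carries a significance
    flag at that level.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    if covariates is None or (hasattr(covariates, "shape") and covariates.shape[1] == 0):
        cov = np.ones((n, 1))
        names: list[str] = []
        k = 0
    else:
        covariates = pd.DataFrame(covariates)
        names = list(covariates.columns)
        k = covariates.shape[1]
        cov = np.column_stack([np.ones(n), covariates.to_numpy(dtype=float)])
    if n <= k + 2:
        raise ValueError("need n > number of covariates + 2")
    beta_x, *_ = np.linalg.lstsq(cov, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(cov, y, rcond=None)
    rx = x - cov @ beta_x
    ry = y - cov @ beta_y
    sx, sy = rx.std(), ry.std()
    # residuals that are zero up to numerical noise mean x or y is an exact
    # linear function of the covariates: the partial correlation is undefined
    if sx <= 1e-10 * max(1.0, x.std()) or sy <= 1e-10 * max(1.0, y.std()):
        return PartialCorr(r=float("nan"), p=float("nan"), n=n, covariates=names,
                           alpha_adjusted=alpha_adjusted, significant=None)
    r = float(np.dot(rx - rx.mean(), ry - ry.mean()) / (n * rx.std() * ry.std()))
    r = max(-1.0, min(1.0, r))
    df = n - k - 2
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2 * stats.t.sf(abs(t), df))
    sig = None if alpha_adjusted is None else bool(p < alpha_adjusted)
    return PartialCorr(r=r, p=p, n=n, covariates=names,
                       alpha_adjusted=alpha_adjusted, significant=sig)


def bonferroni(alpha_family: float, m: int) -> float:
    """Per-test alpha for m comparisons at family level ``alpha_family``."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha_family / m


# ---------------------------------------------------------------------------
# Fisher r-to-z


@dataclass
class FisherZComparison:
    z: float
    p: float
    r1: float
    n1: int
    r2: float
    n2: int


def fisher_r_to_z(r1: float, n1: int, r2: float, n2: int) -> FisherZComparison:
    """Compare two independent correlations via the Fisher z transform:
    ``z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3))``, two-sided p."""
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("|r| must be < 1 for the Fisher transform")
    for n in (n1, n2):
        if n <= 3:
            raise ValueError("each group needs n > 3")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = float(2 * stats.norm.sf(abs(z)))
    return FisherZComparison(z=float(z), p=p, r1=r1, n1=n1, r2=r2, n2=n2)


# ---------------------------------------------------------------------------
# permutation subsampling


@dataclass
class PermutationSummary:
    mean_beta: float
    ci_lower: float
    ci_upper: float
    frac_significant: float
    n_perm: int
    n_subsample: int
    betas: np.ndarray


def permutation_subsample_test(
    cohort: pd.DataFrame,
    n_subsample: int,
    n_perm: int,
    seed: int,
    response: str = "sri",
    group_col: str = "group",
    covariate_cols: tuple[str, ...] = ("age", "sex_female"),
) -> PermutationSummary:
    """Refit the group model on random subsamples of the larger (group=1) arm.

    Each permutation draws ``n_subsample`` group-1 rows without replacement,
    keeps all group-0 rows, refits OLS of ``response`` on group + covariates,
    and records the group beta and its p-value. Randomness is split
    hierarchically per permutation from ``seed`` so results do not depend on
    iteration order.
    """
    g1 = cohort[cohort[group_col] == 1]
    g0 = cohort[cohort[group_col] == 0]
    if n_subsample > len(g1):
        raise ValueError("n_subsample exceeds the size of the subsampled group")
    children = np.random.SeedSequence(seed).spawn(n_perm)
    betas = np.empty(n_perm)
    pvals = np.empty(n_perm)
    for i, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        take = rng.choice(len(g1), size=n_subsample, replace=False)
        sub = pd.concat([g1.iloc[np.sort(take)], g0], ignore_index=True)
        fit = fit_ols(sub[response], sub[[group_col, *covariate_cols]])
        betas[i] = fit.params[group_col]
        pvals[i] = fit.pvalues[group_col]
    lo, hi = np.percentile(betas, [2.5, 97.5])
    return PermutationSummary(
        mean_beta=float(betas.mean()),
        ci_lower=float(lo),
        ci_upper=float(hi),
        frac_significant=float(np.mean(pvals < 0.05)),
        n_perm=n_perm,
        n_subsample=n_subsample,
        betas=betas,
    )


# ---------------------------------------------------------------------------
# sensitivity power analysis


@dataclass
class PowerSpec:
    alpha: float
    power: float
    total_n: int
    n_groups: int
    n_covariates: int
    numerator_df: int
    denominator_df: int
    f: float  # solved Cohen's f
    lambda_convention: str = "total_n"


def _ancova_power(f: float, alpha: float, total_n: int, df1: int, df2: int,
                  lambda_n: float) -> float:
    crit = stats.f.isf(alpha, df1, df2)
    lam = f * f * lambda_n
    if lam == 0:  # ncf is numerically unreliable at zero noncentrality
        return float(stats.f.sf(crit, df1, df2))
    return float(stats.ncf.sf(crit, df1, df2, lam))


def sensitivity_power_ancova(
    alpha: float,
    power: float,
    total_n: int,
    n_groups: int,
    n_covariates: int,
    lambda_convention: str = "total_n",
) -> PowerSpec:
    """Smallest detectable Cohen's f for an ANCOVA-style F test.

    Solves for f such that the F test with numerator df ``n_groups - 1``,
    denominator df ``total_n - n_groups - n_covariates`` and noncentrality
    ``lambda = f^2 * N`` attains the requested power at ``alpha``. Two
    noncentrality conventions are exposed: ``"total_n"`` (lambda = f^2 * N,
    the G*Power fixed-effects convention, default) and ``"df"``
    (lambda = f^2 * (df1 + df2 + 1), the Cohen-tables convention); they agree
    to well under one percent at cohort-scale N. The root is located to a
    power error below 1e-9.
    """
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    df1 = n_groups - 1
    df2 = total_n - n_groups - n_covariates
    if df1 < 1 or df2 < 1:
        raise ValueError("invalid degrees of freedom for this design")
    if lambda_convention == "total_n":
        lambda_n = float(total_n)
    elif lambda_convention == "df":
        lambda_n = float(df1 + df2 + 1)
    else:
        raise ValueError("lambda_convention must be 'total_n' or 'df'")
    lo, hi = 0.0, 10.0
    if _ancova_power(hi, alpha, total_n, df1, df2, lambda_n) < power:
        raise ValueError("requested power unattainable within f <= 10")
    f = optimize.brentq(
        lambda f_: _ancova_power(f_, alpha, total_n, df1, df2, lambda_n) - power,
        lo, hi, xtol=1e-12, rtol=8.9e-16,
    )
    return PowerSpec(
        alpha=alpha,
        power=power,
        total_n=total_n,
        n_groups=n_groups,
        n_covariates=n_covariates,
        numerator_df=df1,
        denominator_df=df2,
        f=float(f),
        lambda_convention=lambda_convention,
    )


def label_correlation_strength(r: float) -> str:
    """Guideline label on |r|: < 0.4 weak; 0.4–0.7 moderate; > 0.7 strong."""
    if abs(r) > 1:
        raise ValueError("|r| must be <= 1")
    a = abs(r)
    if a < 0.4:
        return "weak"
    if a <= 0.7:
        return "moderate"
    return "strong"


# ---------------------------------------------------------------------------
# assumption diagnostics (reported, never silently gatekeeping)


def ancova_interaction_diagnostic(
    cohort: pd.DataFrame,
    response: str = "sri",
    group_col: str = "group",
    covariate_cols: tuple[str, ...] = ("age", "sex_female"),
) -> dict[str, float]:
    """F test of group x covariate interactions (homogeneity of slopes).

    A significant interaction violates the ANCOVA assumption and motivates
    reporting a plain regression instead; this diagnostic only reports.
    """
    X0 = cohort[[group_col, *covariate_cols]].astype(float).copy()
    X1 = X0.copy()
    for c in covariate_cols:
        X1[f"{group_col}:{c}"] = X0[group_col] * X0[c]
    y = cohort[response].astype(float)
    fit0 = sm.OLS(y, sm.add_constant(X0)).fit()
    fit1 = sm.OLS(y, sm.add_constant(X1)).fit()
    f_stat, p_val, df_diff = fit1.compare_f_test(fit0)
    return {"f": float(f_stat), "p": float(p_val), "df_num": float(df_diff)}


def residual_normality_diagnostic(fit: OlsFit, response, design: pd.DataFrame) -> dict[str, float]:
    """Shapiro–Wilk test on the OLS residuals (diagnostic report only)."""
    y = np.asarray(response, dtype=float)
    Xc = sm.add_constant(pd.DataFrame(design).astype(float), has_constant="add")
    resid = y - Xc.to_numpy() @ np.concatenate(
        [[fit.params["const"]], [fit.params[c] for c in design.columns]]
    )
    w, p = stats.shapiro(resid)
    return {"w": float(w), "p": float(p)}
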