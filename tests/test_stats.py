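"""Statistical operations against independent oracles and closed forms."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sleepreg.stats import (
    bonferroni,
    chi_square_2x2,
    fisher_r_to_z,
    fit_ols,
    label_correlation_strength,
    partial_pearson,
    permutation_subsample_test,
    sensitivity_power_ancova,
    welch_t,
)


class TestWelchT:
    def test_hand_computed_example(self):
        t, df, p = welch_t([1, 2, 3], [2, 4, 6])
        assert t == pytest.approx(-1.549, abs=1e-3)
        assert df == pytest.approx(2.94, abs=0.01)

    def test_identical_samples_give_zero(self):
        t, _, p = welch_t([1, 2, 3, 4], [1, 2, 3, 4])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_equal_variance_limit_matches_pooled_t(self, rng):
        x = rng.normal(0, 1, 400)
        y = rng.normal(0.1, 1, 400)
        t_w, df_w, p_w = welch_t(x, y)
        pooled = sps.ttest_ind(x, y, equal_var=True)
        assert t_w == pytest.approx(pooled.statistic, abs=1e-6)
        assert p_w == pytest.approx(pooled.pvalue, rel=1e-3)

    def test_degenerate_equal_constants_reported_undefined(self):
        t, df, p = welch_t([2.0, 2.0], [2.0, 2.0])
        assert np.isnan(t) and np.isnan(p)


class TestChiSquare:
    def test_cohort_sex_table(self):
        chi2, p = chi_square_2x2(np.array([[73, 89], [28, 32]]))
        assert chi2 == pytest.approx(3.78e-03, abs=5e-6)
        assert p == pytest.approx(0.951, abs=1e-3)

    def test_proportional_rows_uncorrected_zero(self):
        chi2, _ = chi_square_2x2(np.array([[10, 20], [10, 20]]), continuity=False)
        assert chi2 == pytest.approx(0.0)

    def test_hand_computed_with_correction(self):
        # E = 15 everywhere; sum((|O-E|-0.5)^2 / E) = 4 * 4.5^2 / 15 = 5.4
        chi2, _ = chi_square_2x2(np.array([[10, 20], [20, 10]]))
        assert chi2 == pytest.approx(5.4)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2(np.array([[0, 0], [5, 5]]))


class TestFitOls:
    def test_noiseless_group_effect_recovered_exactly(self):
        group = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        y = 50.0 - 6.0 * group
        fit = fit_ols(y, pd.DataFrame({"group": group}))
        assert fit.params["group"] == pytest.approx(-6.0, abs=1e-10)
        assert fit.params["const"] == pytest.approx(50.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_duplicate_column_raises_rank_error(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        X = pd.DataFrame({"a": x, "b": x})
        with pytest.raises(ValueError, match="collinear.*b"):
            fit_ols(rng.normal(size=20), X)

    def test_wald_ci_brackets_estimate_and_matches_t(self, rng):
        n = 120
        X = pd.DataFrame({"x1": rng.normal(size=n), "g": rng.integers(0, 2, n)})
        y = 2.0 + 1.5 * X["x1"] - 0.8 * X["g"] + rng.normal(0, 1, n)
        fit = fit_ols(y, X)
        for name in ("x1", "g"):
            lo, hi = fit.conf_int.loc[name]
            assert lo < fit.params[name] < hi
        assert fit.nobs == n and fit.df_resid == n - 3

    def test_standardized_beta_equals_r_for_single_predictor(self, rng):
        x = rng.normal(size=200)
        y = 0.5 * x + rng.normal(0, 1, 200)
        fit = fit_ols(y, pd.DataFrame({"x": x}))
        r = np.corrcoef(x, y)[0, 1]
        assert fit.std_params["x"] == pytest.approx(r, abs=1e-10)


class TestPartialPearson:
    def test_reduces_to_plain_pearson_without_covariates(self, rng):
        x = rng.normal(size=50)
        y = x + rng.normal(0, 1, 50)
        pc = partial_pearson(x, y)
        r_ref, p_ref = sps.pearsonr(x, y)
        assert pc.r == pytest.approx(r_ref, abs=1e-12)
        assert pc.p == pytest.approx(p_ref, rel=1e-9)

    def test_perfect_dependence(self, rng):
        x = rng.normal(size=30)
        cov = pd.DataFrame({"z": rng.normal(size=30)})
        pc = partial_pearson(x, x.copy(), cov)
        assert pc.r == pytest.approx(1.0)

    def test_matrix_inversion_oracle(self, rng):
        """Residual method equals inverting the correlation matrix."""
        for _ in range(20):
            n = 8 + int(rng.integers(0, 40))
            x = rng.normal(size=n)
            z = rng.normal(size=n)
            y = 0.4 * x + 0.6 * z + rng.normal(0, 1, n)
            pc = partial_pearson(x, y, pd.DataFrame({"z": z}))
            corr = np.corrcoef(np.vstack([x, y, z]))
            prec = np.linalg.inv(corr)
            r_oracle = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
            assert pc.r == pytest.approx(r_oracle, abs=1e-10)

    def test_agrees_with_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        n = 60
        df = pd.DataFrame(
            {
                "x": rng.normal(size=n),
                "y": rng.normal(size=n),
                "age": rng.normal(60, 10, n),
                "sex": rng.integers(0, 2, n),
            }
        )
        df["y"] += 0.3 * df["x"] - 0.02 * df["age"]
        pc = partial_pearson(df["x"], df["y"], df[["age", "sex"]])
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["age", "sex"])
        assert pc.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert pc.p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)
        assert pc.n == n

    def test_constant_residuals_reported_undefined(self):
        z = np.arange(10.0)
        pc = partial_pearson(2 * z + 1, np.arange(10.0)[::-1], pd.DataFrame({"z": z}))
        assert np.isnan(pc.r)


class TestBonferroni:
    def test_family_of_five(self):
        assert bonferroni(0.05, 5) == pytest.approx(0.01)

    def test_single_test(self):
        assert bonferroni(0.05, 1) == pytest.approx(0.05)

    def test_marginal_result_not_significant_after_correction(self, rng):
        """r = 0.18, p = 0.03 fails at the corrected alpha of 0.01."""
        # construct data with this exact sample correlation
        n = 145
        x = rng.normal(size=n)
        e = rng.normal(size=n)
        e -= e.mean() + x * np.dot(x - x.mean(), e - e.mean()) / np.dot(
            x - x.mean(), x - x.mean()
        )
        target_r = 0.18
        y = target_r * (x - x.mean()) / x.std() + np.sqrt(1 - target_r**2) * (
            e / e.std()
        )
        pc = partial_pearson(x, y, alpha_adjusted=bonferroni(0.05, 5))
        assert pc.r == pytest.approx(0.18, abs=1e-9)
        assert 0.01 < pc.p < 0.05
        assert pc.significant is False


class TestFisherRToZ:
    def test_equal_correlations(self):
        fz = fisher_r_to_z(0.3, 40, 0.3, 60)
        assert fz.z == 0.0
        assert fz.p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        fz = fisher_r_to_z(0.5, 50, 0.2, 50)
        assert fz.z == pytest.approx(1.680, abs=1e-3)

    def test_antisymmetry(self):
        a = fisher_r_to_z(0.5, 50, 0.2, 80)
        b = fisher_r_to_z(0.2, 80, 0.5, 50)
        assert a.z == pytest.approx(-b.z)
        assert a.p == pytest.approx(b.p)

    def test_degenerate_r_rejected(self):
        with pytest.raises(ValueError):
            fisher_r_to_z(1.0, 50, 0.2, 50)


class TestPermutationSubsample:
    def _cohort(self, rng, n1=60, n0=30, beta=-6.0):
        group = np.r_[np.ones(n1), np.zeros(n0)]
        age = rng.normal(60, 12, n1 + n0)
        sex = rng.integers(0, 2, n1 + n0)
        sri = 55 + beta * group - 0.1 * age + 4 * sex + rng.normal(0, 8, n1 + n0)
        return pd.DataFrame(
            {"sri": sri, "group": group.astype(int), "age": age, "sex_female": sex}
        )

    def test_full_subsample_equals_full_fit(self, rng):
        df = self._cohort(rng)
        full = fit_ols(df["sri"], df[["group", "age", "sex_female"]])
        perm = permutation_subsample_test(df, n_subsample=60, n_perm=1, seed=3)
        assert perm.mean_beta == pytest.approx(full.params["group"], abs=1e-10)

    def test_deterministic_under_seed(self, rng):
        df = self._cohort(rng)
        a = permutation_subsample_test(df, n_subsample=30, n_perm=50, seed=11)
        b = permutation_subsample_test(df, n_subsample=30, n_perm=50, seed=11)
        np.testing.assert_array_equal(a.betas, b.betas)

    def test_subsampling_unbiased_for_full_estimate(self, rng):
        df = self._cohort(rng, n1=162, n0=60)
        full = fit_ols(df["sri"], df[["group", "age", "sex_female"]])
        perm = permutation_subsample_test(df, n_subsample=60, n_perm=500, seed=5)
        assert perm.mean_beta == pytest.approx(full.params["group"], abs=1.0)


class TestSensitivityPower:
    def test_null_limit_gives_alpha(self):
        from sleepreg.stats import _ancova_power

        assert _ancova_power(0.0, 0.05, 254, 1, 250, 254.0) == pytest.approx(0.05)

    def test_monotone_decreasing_in_n(self):
        fs = [
            sensitivity_power_ancova(0.05, 0.80, n, 2, 2).f
            for n in (100, 200, 400, 800)
        ]
        assert all(a > b for a, b in zip(fs, fs[1:]))

    def test_lambda_conventions_agree_at_cohort_scale(self):
        a = sensitivity_power_ancova(0.05, 0.80, 254, 2, 2, "total_n")
        b = sensitivity_power_ancova(0.05, 0.80, 254, 2, 2, "df")
        assert a.f == pytest.approx(b.f, rel=0.01)

    def test_achieved_power_by_monte_carlo_ancova(self):
        """Simulated ANCOVA rejection rate at the solved f is the target power."""
        spec = sensitivity_power_ancova(0.05, 0.80, 254, 2, 2)
        rng = np.random.default_rng(314159)
        n = 254
        half = n // 2
        d = 2.0 * spec.f  # two equal groups at +/- f sigma
        crit = sps.f.isf(0.05, 1, n - 4)
        group = np.r_[np.zeros(half), np.ones(n - half)]
        rejections = 0
        reps = 8000
        for _ in range(reps):
            cov = rng.normal(size=(n, 2))
            y = d * group + rng.normal(size=n)
            X1 = np.column_stack([np.ones(n), group, cov])
            X0 = np.column_stack([np.ones(n), cov])
            rss1 = np.sum((y - X1 @ np.linalg.lstsq(X1, y, rcond=None)[0]) ** 2)
            rss0 = np.sum((y - X0 @ np.linalg.lstsq(X0, y, rcond=None)[0]) ** 2)
            F = (rss0 - rss1) / (rss1 / (n - 4))
            rejections += F > crit
        assert rejections / reps == pytest.approx(0.80, abs=0.02)


class TestCorrelationStrengthLabels:
    @pytest.mark.parametrize(
        "r,label",
        [(0.25, "weak"), (0.39, "weak"), (0.4, "moderate"), (0.7, "moderate"),
         (0.71, "strong"), (-0.75, "strong")],
    )
    def test_guideline_boundaries(self, r, label):
        assert label_correlation_strength(r) == label
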