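"""Contrast statistics: t-values, Wilcoxon signed-rank Z, Gaussian GLM."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as st

from riskcog.risk_stats import (
    adjust_pvalues,
    episode_tvalue,
    glm_gaussian,
    grouped_summary,
    risk_mean_test,
    wilcoxon_z,
)


class TestEpisodeTvalue:
    def test_hand_computed_paired(self):
        res = episode_tvalue([0.0, 1.0, 2.0], [1.0, 3.0, 5.0])
        assert res.statistic == pytest.approx(2.0 / (1.0 / np.sqrt(3)), rel=1e-9)
        assert res.kind == "paired-t"

    def test_identical_groups_degenerate_zero(self):
        x = [0.3, 0.5, 0.9]
        with pytest.warns(UserWarning):
            res = episode_tvalue(x, x)
        assert res.statistic == 0.0 and res.p_value == 1.0 and res.degenerate

    def test_swap_negates(self, rng):
        low, high = rng.standard_normal((2, 15))
        a = episode_tvalue(low, high).statistic
        b = episode_tvalue(high, low).statistic
        assert a == pytest.approx(-b, rel=1e-12)

    def test_matches_first_principles_and_scipy(self, rng):
        """Paired t equals both a hand formula and scipy on random inputs."""
        for _ in range(25):
            n = rng.integers(3, 40)
            low, high = rng.standard_normal((2, n))
            res = episode_tvalue(low, high)
            d = high - low
            brute = d.mean() / np.sqrt(d.var(ddof=1) / n)
            assert res.statistic == pytest.approx(brute, abs=1e-10)
            ref = st.ttest_rel(high, low)
            assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_independent_modes(self, rng):
        low = rng.standard_normal(10)
        high = rng.standard_normal(14) + 1
        res = episode_tvalue(low, high, mode="independent")
        ref = st.ttest_ind(high, low, equal_var=True)
        assert res.statistic == pytest.approx(ref.statistic)
        res_w = episode_tvalue(low, high, mode="welch")
        ref_w = st.ttest_ind(high, low, equal_var=False)
        assert res_w.statistic == pytest.approx(ref_w.statistic)

    def test_zero_variance_diff_is_inf_sentinel(self):
        with pytest.warns(UserWarning):
            res = episode_tvalue([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
        assert np.isinf(res.statistic) and res.statistic > 0 and res.degenerate


class TestRiskMeanTest:
    def test_constant_series_table_shape(self):
        with pytest.warns(UserWarning):
            res = risk_mean_test([0.01] * 5, [0.128] * 5)
        assert res.m_low == pytest.approx(0.01)
        assert res.m_high == pytest.approx(0.128)
        assert res.d_lh == pytest.approx(0.118)
        assert res.contrast.degenerate

    def test_type_one_error_calibration(self):
        """Identical distributions reject at ~5% over 1000 simulations."""
        rng = np.random.default_rng(99)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            low = rng.standard_normal(20)
            high = rng.standard_normal(20)
            if risk_mean_test(low, high).contrast.p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_sim <= 0.07

    def test_positive_difference_by_construction(self, rng):
        low = rng.uniform(0.0, 0.05, 12)
        high = rng.uniform(0.06, 0.2, 12)
        assert risk_mean_test(low, high).d_lh > 0


class TestWilcoxonZ:
    @pytest.mark.parametrize(
        "pos_ranks,expected_z",
        [({1, 4}, -1.521), ({4, 7}, -0.507)],
    )
    def test_small_sample_z_values(self, pos_ranks, expected_z):
        """n=7, no ties: positive-rank sums 5 and 11 give the printed Z."""
        diffs = [(0.1 * r if r in pos_ranks else -0.1 * r) for r in range(1, 8)]
        res = wilcoxon_z(diffs=diffs)
        assert round(res.statistic, 3) == expected_z

    def test_z_never_positive(self, rng):
        for _ in range(30):
            d = rng.standard_normal(rng.integers(3, 20))
            res = wilcoxon_z(diffs=d)
            assert res.statistic <= 0

    @pytest.mark.parametrize("n", [4, 7, 10])
    def test_exhaustive_enumeration_moments(self, n):
        """Mean/variance of W over all 2^n sign patterns match the formula."""
        mags = np.arange(1.0, n + 1)  # distinct magnitudes, ranks 1..n
        ws = []
        for signs in itertools.product([1, -1], repeat=n):
            d = mags * np.array(signs)
            ranks = st.rankdata(np.abs(d))
            ws.append(ranks[d > 0].sum())
        ws = np.array(ws)
        assert ws.mean() == pytest.approx(n * (n + 1) / 4)
        assert ws.var() == pytest.approx(n * (n + 1) * (2 * n + 1) / 24)

    def test_standardized_statistic_enumeration(self):
        """Z computed from W+ has mean 0, variance 1 under enumeration."""
        n = 7
        mean_w = n * (n + 1) / 4
        var_w = n * (n + 1) * (2 * n + 1) / 24
        zs = []
        for signs in itertools.product([1, -1], repeat=n):
            d = np.arange(1.0, n + 1) * np.array(signs)
            ranks = st.rankdata(np.abs(d))
            zs.append((ranks[d > 0].sum() - mean_w) / np.sqrt(var_w))
        zs = np.array(zs)
        assert zs.mean() == pytest.approx(0.0, abs=1e-12)
        assert zs.var() == pytest.approx(1.0, rel=1e-12)

    def test_matches_scipy_magnitude(self, rng):
        """|Z| agrees with scipy's normal-approximation Wilcoxon."""
        for _ in range(10):
            d = rng.standard_normal(25)
            res = wilcoxon_z(diffs=d)
            ref = st.wilcoxon(d, correction=False, method="approx")
            assert abs(res.statistic) == pytest.approx(abs(ref.zstatistic), abs=1e-9)

    def test_ties_use_average_ranks_and_correction(self):
        d = np.array([1.0, 1.0, -1.0, 2.0, -2.0, 3.0])
        res = wilcoxon_z(diffs=d)
        ref = st.wilcoxon(d, correction=False, method="approx")
        assert abs(res.statistic) == pytest.approx(abs(ref.zstatistic), abs=1e-9)

    def test_zeros_dropped_and_degenerate(self):
        with pytest.warns(UserWarning):
            res = wilcoxon_z(diffs=[0.0, 0.0])
        assert res.degenerate


class TestGlmGaussian:
    def test_intercept_only_closed_form(self):
        fit = glm_gaussian([1.0, 2.0, 3.0], np.ones((3, 1)))
        assert fit.params[0] == pytest.approx(2.0)
        assert fit.scale == pytest.approx(2.0 / 3.0)
        assert fit.se[0] == pytest.approx(0.47140, abs=1e-5)
        assert fit.wald_chi2[0] == pytest.approx(18.0, abs=1e-9)
        assert fit.ci_lower[0] == pytest.approx(1.0760, abs=1e-4)
        assert fit.ci_upper[0] == pytest.approx(2.9240, abs=1e-4)
        assert fit.names == ["(Intercept)"]

    def test_perfect_fit_flag(self):
        x = np.arange(1.0, 6.0)
        fit = glm_gaussian(2 * x, x[:, None])
        assert fit.params[0] == pytest.approx(2.0)
        assert fit.perfect_fit

    def test_wald_and_ci_identities(self, rng):
        X = np.column_stack([np.ones(50), rng.standard_normal(50)])
        y = X @ [1.0, 0.5] + rng.standard_normal(50)
        fit = glm_gaussian(y, X)
        assert np.allclose(fit.wald_chi2, (fit.params / fit.se) ** 2)
        assert np.allclose(fit.ci_lower, fit.params - 1.959964 * fit.se)
        assert np.allclose(fit.ci_upper, fit.params + 1.959964 * fit.se)
        assert np.all(fit.ci_lower <= fit.params) and np.all(fit.params <= fit.ci_upper)

    def test_parameter_recovery_seeded(self):
        """Recovers an intercept of 0.069 and ML scale 0.002 at n=5000."""
        rng = np.random.default_rng(7)
        y = 0.069 + rng.normal(0.0, np.sqrt(0.002), 5000)
        fit = glm_gaussian(y, np.ones((5000, 1)))
        assert abs(fit.params[0] - 0.069) < 0.005
        assert abs(fit.scale - 0.002) < 0.2 * 0.002

    def test_matches_statsmodels_up_to_scale_convention(self, rng):
        """B equals the statsmodels GLM fit; SE differs only by ML vs df scale."""
        import statsmodels.api as sm

        n = 80
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ [0.5, -1.2] + rng.standard_normal(n)
        fit = glm_gaussian(y, X)
        ref = sm.GLM(y, X, family=sm.families.Gaussian()).fit()
        assert np.allclose(fit.params, ref.params, atol=1e-10)
        # statsmodels uses RSS/(n-p); ours is the ML scale RSS/n
        adj = np.sqrt(n / (n - 2))
        assert np.allclose(fit.se * adj, ref.bse, rtol=1e-8)

    def test_rank_deficient_design_names_columns(self):
        X = np.column_stack([np.ones(10), np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValueError, match="collinear"):
            glm_gaussian(np.arange(10.0), X, names=["c0", "c1", "c2"])

    def test_summary_frame_shape(self):
        fit = glm_gaussian([1.0, 2.0, 3.0, 4.0], np.ones((4, 1)))
        frame = fit.summary_frame()
        assert list(frame["Parameter"]) == ["(Intercept)", "(Scale)"]
        assert {"B", "Std error", "Wald chi-square", "df", "Sig"} <= set(frame.columns)


class TestGroupedSummary:
    def _df(self, values, group, risk_class):
        return pd.DataFrame({"value": values, "sex": group, "risk_class": risk_class})

    def test_known_five_number_summary(self):
        df = self._df(list(range(1, 10)), ["m"] * 9, ["low"] * 9)
        out = grouped_summary(df, "sex")
        row = out.iloc[0]
        assert (row["min"], row["q1"], row["median"], row["q3"], row["max"]) == (1, 3, 5, 7, 9)

    def test_identical_values_collapse(self):
        df = self._df([2.0] * 6, ["f"] * 6, ["high"] * 6)
        row = grouped_summary(df, "sex").iloc[0]
        assert row["min"] == row["q1"] == row["median"] == row["q3"] == row["max"] == 2.0

    def test_singleton_group_flagged(self):
        df = self._df([1.0], ["m"], ["low"])
        assert bool(grouped_summary(df, "sex").iloc[0]["degenerate"])

    def test_missing_grouping_column(self):
        with pytest.raises(KeyError):
            grouped_summary(self._df([1.0], ["m"], ["low"]), "driving_experience")


def test_pvalue_adjustment_is_conservative(rng):
    p = rng.uniform(0, 1, 8)
    bonf = adjust_pvalues(p, "bonferroni")
    assert np.all(bonf >= p - 1e-12)
    assert np.allclose(bonf, np.minimum(p * 8, 1.0))
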