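import numpy as np
import pandas as pd
import pytest

from fluxconverge.stats import (
    SingularDesignError, UndefinedAxisError, group_compare, ma_regression,
    outlier_sensitivity, paired_compare, significance_marker, two_way_anova,
    weighted_screen,
)


def eigen_ma_slope(x, y):
    """Independent oracle: slope of the leading eigenvector of cov(x, y)."""
    cov = np.cov(x, y, ddof=1)
    vals, vecs = np.linalg.eigh(cov)
    v = vecs[:, np.argmax(vals)]
    return v[1] / v[0]


def wls_normal_equations(x, y, w):
    """Independent oracle: weighted normal equations for intercept + slope."""
    X = np.column_stack([np.ones_like(x), x])
    W = np.diag(w)
    return np.linalg.solve(X.T @ W @ X, X.T @ W @ y)


class TestMaRegression:
    def test_perfect_line_recovered_exactly(self):
        x = np.array([1.0, 2, 3, 4, 5])
        res = ma_regression(x, 2 * x + 3)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(3.0)
        assert res.r_squared == pytest.approx(1.0)
        lo, hi = res.slope_ci95
        assert hi - lo == pytest.approx(0.0, abs=1e-9)

    def test_matches_eigen_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 15))
            x = rng.normal(0, 2, n)
            y = 0.8 * x + rng.normal(0, 1, n)
            res = ma_regression(x, y)
            assert res.slope == pytest.approx(eigen_ma_slope(x, y), abs=1e-10)

    def test_axis_swap_reciprocity(self, rng):
        x = rng.normal(0, 1, 20)
        y = 1.4 * x + rng.normal(0, 0.5, 20)
        assert ma_regression(x, y).slope * ma_regression(y, x).slope \
            == pytest.approx(1.0, abs=1e-10)

    def test_slope_between_ols_and_inverse_ols(self, rng):
        x = rng.normal(0, 1, 40)
        y = x + rng.normal(0, 0.8, 40)
        b_ols = np.polyfit(x, y, 1)[0]
        b_inv = 1.0 / np.polyfit(y, x, 1)[0]
        b_ma = ma_regression(x, y).slope
        assert min(b_ols, b_inv) <= b_ma <= max(b_ols, b_inv)

    def test_invariant_under_translation_and_common_scaling(self, rng):
        x = rng.normal(5, 2, 25)
        y = 0.9 * x + rng.normal(0, 1, 25)
        b = ma_regression(x, y).slope
        assert ma_regression(x + 100, y - 50).slope == pytest.approx(b, abs=1e-10)
        assert ma_regression(3 * x, 3 * y).slope == pytest.approx(b, abs=1e-10)

    def test_analytic_ci_consistent_with_bootstrap(self, rng):
        x = rng.normal(0, 1, 40)
        y = x + rng.normal(0, 0.6, 40)
        res = ma_regression(x, y)
        lo, hi = res.slope_ci95
        assert lo <= res.slope <= hi
        # dual route: percentile bootstrap should roughly agree
        slopes = []
        for _ in range(500):
            idx = rng.integers(0, 40, 40)
            slopes.append(eigen_ma_slope(x[idx], y[idx]))
        blo, bhi = np.percentile(slopes, [2.5, 97.5])
        assert lo == pytest.approx(blo, abs=0.15)
        assert hi == pytest.approx(bhi, abs=0.2)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ma_regression([1, 2], [1, 2])
        with pytest.raises(UndefinedAxisError):
            ma_regression([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
        # circular scatter: Sxy = 0, Sxx = Syy
        with pytest.raises(UndefinedAxisError):
            ma_regression([1.0, -1.0, 0.0, 0.0], [0.0, 0.0, 1.0, -1.0])


class TestPairedCompare:
    def test_identical_samples_degenerate(self):
        a = np.arange(5.0)
        res = paired_compare(a, a)
        assert res.mean_difference == 0.0
        assert res.p_value == 1.0
        assert res.test_used == "degenerate"

    def test_shifted_normal_detected_with_t(self, rng):
        a = rng.normal(1.0, 1.0, 30)
        b = np.zeros(30)
        res = paired_compare(a, b)
        assert res.test_used == "paired_t"
        assert res.p_value < 0.05
        assert res.mean_difference == pytest.approx(a.mean())

    def test_skewed_differences_fall_back_to_wilcoxon(self, rng):
        d = rng.exponential(1.0, 40) ** 3  # strongly non-normal
        res = paired_compare(d, np.zeros(40))
        assert res.shapiro_p < 0.05
        assert res.test_used == "wilcoxon_signed_rank"
        assert res.p_value < 0.01

    def test_matches_scipy_oracles(self, rng):
        from scipy import stats as sps
        a = rng.normal(0.5, 1, 12)
        b = rng.normal(0.0, 1, 12)
        res = paired_compare(a, b)
        if res.test_used == "paired_t":
            assert res.p_value == pytest.approx(sps.ttest_rel(a, b).pvalue)


class TestGroupCompare:
    def test_identical_groups_p_one(self):
        res = group_compare([1.0, 2, 3], [3.0, 2, 1])
        assert res.p_value == 1.0

    def test_separated_groups_significant(self, rng):
        res = group_compare(rng.normal(0, 1, 10), rng.normal(3, 1, 10))
        assert res.p_value < 0.01
        assert res.test_used == "welch_t"

    def test_zero_variance_group_uses_permutation(self):
        res = group_compare([2.0, 2.0], [5.0, 6.0, 7.0])
        assert res.test_used == "permutation"
        assert 0.0 < res.p_value <= 1.0


class TestWeightedScreen:
    def test_exact_linear_response(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        res = weighted_screen(2 * x + 1, x, np.array([1.0, 2, 1, 2, 1, 2]))
        assert res.r_squared == pytest.approx(1.0)
        assert res.p_value < 1e-8
        assert res.slope == pytest.approx(2.0)

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.normal(0, 1, 15)
        y = 1.5 * x + rng.normal(0, 0.5, 15)
        w = rng.uniform(0.5, 2.0, 15)
        res = weighted_screen(y, x, w)
        beta = wls_normal_equations(x, y, w)
        assert res.intercept == pytest.approx(beta[0], abs=1e-10)
        assert res.slope == pytest.approx(beta[1], abs=1e-10)

    def test_unit_weights_equal_ols(self, rng):
        x = rng.normal(0, 1, 20)
        y = x + rng.normal(0, 1, 20)
        res = weighted_screen(y, x, np.ones(20))
        b = np.polyfit(x, y, 1)
        assert res.slope == pytest.approx(b[0], abs=1e-10)
        assert res.intercept == pytest.approx(b[1], abs=1e-10)

    def test_weight_power_switch_matches_inverse_variance(self, rng):
        x = rng.normal(0, 1, 20)
        y = x + rng.normal(0, 1, 20)
        s = rng.uniform(0.5, 2.0, 20)
        res2 = weighted_screen(y, x, 1 / s, weight_power=2.0)
        beta = wls_normal_equations(x, y, 1 / s**2)
        assert res2.slope == pytest.approx(beta[1], abs=1e-10)

    def test_categorical_predictor_overall_f_test(self, rng):
        groups = np.repeat(["a", "b", "c"], 8)
        y = np.where(groups == "c", 3.0, 0.0) + rng.normal(0, 0.5, 24)
        res = weighted_screen(y, groups, np.ones(24))
        assert res.p_value < 1e-4
        assert np.isnan(res.slope)  # no single slope for a 3-level factor

    def test_heteroskedastic_case_flagged_with_robust_inference(self, rng):
        x = np.linspace(1, 10, 60)
        y = 0.5 * x + rng.normal(0, 0.2 * x**2, 60)
        res = weighted_screen(y, x, np.ones(60))
        assert res.heteroskedastic
        assert res.inference_method == "white_robust"

    def test_constant_predictor_rejected(self):
        with pytest.raises(SingularDesignError):
            weighted_screen([1.0, 2, 3, 4], np.ones(4), np.ones(4))

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            weighted_screen([1.0, 2, 3, 4], [1.0, 2, 3, 4], [1.0, 0.0, 1, 1])


class TestTwoWayAnova:
    def test_balanced_design_matches_hand_sums_of_squares(self):
        # 2 x 2 with r = 3 replicates; additive A effect of 4, B effect of 2
        a = np.repeat(["a1", "a2"], 6)
        b = np.tile(np.repeat(["b1", "b2"], 3), 2)
        base = {"a1": 0.0, "a2": 4.0}
        off = {"b1": 0.0, "b2": 2.0}
        eps = np.array([0.1, -0.2, 0.1, 0.0, 0.2, -0.1,
                        -0.1, 0.0, 0.1, 0.2, -0.2, 0.0])
        y = np.array([base[ai] + off[bi] for ai, bi in zip(a, b)]) + eps
        res = two_way_anova(y, a, b)
        # hand-computed type-II sums of squares for the balanced 2x2:
        # SS_A = 12 * mean^2 contrast; verify against direct cell means
        ybar = y.mean()
        ss_a = sum(6 * (y[a == lvl].mean() - ybar) ** 2 for lvl in ("a1", "a2"))
        ss_b = sum(6 * (y[b == lvl].mean() - ybar) ** 2 for lvl in ("b1", "b2"))
        cell_means = {(ai, bi): y[(a == ai) & (b == bi)].mean()
                      for ai in ("a1", "a2") for bi in ("b1", "b2")}
        ss_cells = sum(3 * (m - ybar) ** 2 for m in cell_means.values())
        ss_ab = ss_cells - ss_a - ss_b
        ss_err = sum((y[(a == ai) & (b == bi)] - cell_means[(ai, bi)]) ** 2
                     for ai in ("a1", "a2") for bi in ("b1", "b2")).sum()
        from scipy.stats import f as fdist
        p_a_hand = float(fdist.sf((ss_a / 1) / (ss_err / 8), 1, 8))
        p_b_hand = float(fdist.sf((ss_b / 1) / (ss_err / 8), 1, 8))
        p_ab_hand = float(fdist.sf((ss_ab / 1) / (ss_err / 8), 1, 8))
        assert res.p_a == pytest.approx(p_a_hand, abs=1e-10)
        assert res.p_b == pytest.approx(p_b_hand, abs=1e-10)
        assert res.p_interaction == pytest.approx(p_ab_hand, abs=1e-10)

    def test_single_active_factor(self, rng):
        a = np.repeat(["x", "y"], 10)
        b = np.tile(["u", "v"], 10)
        y = np.where(a == "y", 5.0, 0.0) + rng.normal(0, 0.3, 20)
        res = two_way_anova(y, a, b)
        assert res.p_a < 1e-6
        assert res.p_b > 0.1
        assert res.p_interaction > 0.05

    def test_constant_response_degenerate(self):
        res = two_way_anova(np.ones(8), ["a"] * 4 + ["b"] * 4,
                            ["u", "v"] * 4)
        assert res.degenerate
        assert np.isnan(res.p_a)

    def test_empty_crossing_interaction_not_estimable(self, rng):
        a = ["a1"] * 6 + ["a2"] * 3
        b = ["b1", "b2"] * 3 + ["b1"] * 3  # (a2, b2) never observed
        y = rng.normal(0, 1, 9)
        res = two_way_anova(y, a, b)
        assert not res.interaction_estimable
        assert np.isnan(res.p_interaction)
        assert np.isfinite(res.p_a)


class TestOutlierSensitivity:
    def test_stable_design_not_flagged(self, rng):
        x = rng.normal(0, 1, 25)
        y = 2 * x + rng.normal(0, 0.3, 25)
        sens = outlier_sensitivity(y, x, np.ones(25))
        p_full = sens.attrs["p_full"]
        assert not sens["influential"].any()
        assert np.all(np.abs(sens["p_without"] - p_full) <= 0.2 * max(p_full, 1e-12)
                      + 1e-12)

    def test_planted_leverage_point_flips_significance(self, rng):
        x = rng.normal(0, 1, 12)
        y = rng.normal(0, 1, 12)  # no real relationship
        x = np.append(x, 8.0)
        y = np.append(y, 16.0)    # single point manufactures the trend
        sens = outlier_sensitivity(y, x, np.ones(13))
        p_full = sens.attrs["p_full"]
        assert p_full < 0.10
        assert sens.loc[12, "p_without"] > 0.10
        assert sens.loc[12, "influential"]


def test_significance_markers_tiering():
    assert significance_marker(0.005) == "**"
    assert significance_marker(0.03) == "*"
    assert significance_marker(0.07) == "+"
    assert significance_marker(0.5) == ""
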