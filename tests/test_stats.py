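import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from edahab.errors import DegenerateInputError, ParameterError
from edahab.stats import (
    bonferroni_alpha,
    cohens_d,
    cohens_d_from_summary,
    correlations,
    oneway_anova,
    rm_anova_blocks,
    round_alpha,
    screen_variable,
    shape_zscores,
    winsorize_outliers,
)


class TestShapeZscores:
    def test_symmetric_sample_near_zero(self):
        x = np.random.default_rng(0).normal(size=5000)
        z_s, _ = shape_zscores(x)
        assert abs(z_s) < 2.5

    def test_exponential_sample_strongly_right_skewed(self):
        x = np.random.default_rng(1).exponential(size=500)
        z_s, _ = shape_zscores(x)
        assert z_s > 3.0

    def test_mirroring_flips_skew_sign_exactly(self):
        x = np.random.default_rng(2).exponential(size=100)
        z_s, z_k = shape_zscores(x)
        z_s_m, z_k_m = shape_zscores(-x)
        assert z_s_m == pytest.approx(-z_s)
        assert z_k_m == pytest.approx(z_k)

    def test_degenerate_and_short_inputs(self):
        with pytest.raises(DegenerateInputError):
            shape_zscores(np.full(10, 3.0))
        with pytest.raises(ParameterError):
            shape_zscores([1.0, 2.0, 3.0])


class TestScreenVariable:
    def test_normal_sample_passes_without_transform(self):
        x = np.random.default_rng(3).normal(10, 2, 400)
        out, screen = screen_variable(x, "v")
        assert screen.normal_flag and screen.applied_transform == "none"
        assert np.array_equal(out, x)

    def test_lognormal_sample_gets_log_transform(self):
        x = np.random.default_rng(4).lognormal(2.0, 0.8, 400)
        out, screen = screen_variable(x, "v")
        assert screen.applied_transform == "log"
        assert screen.normal_flag
        np.testing.assert_allclose(out, np.log(x))

    def test_ordinal_variables_never_transformed(self):
        x = np.random.default_rng(5).lognormal(1.0, 1.0, 300)
        out, screen = screen_variable(x, "v", allow_transforms=False)
        assert screen.applied_transform == "none"
        assert not screen.normal_flag


class TestWinsorizeOutliers:
    def test_spec_case_high_outlier_replaced_by_next_plus_unit(self):
        adjusted, idx = winsorize_outliers([1, 2, 3, 4, 100], unit=1)
        assert list(adjusted) == [1, 2, 3, 4, 5]
        assert idx == [4]

    def test_clean_sample_untouched(self):
        x = np.arange(20.0)
        adjusted, idx = winsorize_outliers(x, unit=1)
        assert np.array_equal(adjusted, x) and idx == []

    def test_symmetric_outliers_replaced_symmetrically(self):
        x = np.array([-100.0, 1, 2, 3, 4, 5, 105.0])
        adjusted, idx = winsorize_outliers(x, unit=1)
        assert adjusted[0] == 1 - 1 and adjusted[-1] == 5 + 1
        assert idx == [0, 6]

    def test_rank_order_of_non_outliers_preserved(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(0, 1, 50), [40.0, -40.0]])
        adjusted, idx = winsorize_outliers(x, unit=0.1)
        keep = np.delete(np.arange(x.size), idx)
        assert np.array_equal(np.argsort(adjusted[keep]), np.argsort(x[keep]))

    def test_literal_q1_anchor_mode(self):
        x = np.array([0.0, 10, 11, 12, 13, 14, 20.0])
        # Q1=10.5, Q3=13.5, IQR=3: literal upper fence 10.5+9=19.5 flags 20
        _, idx_default = winsorize_outliers(x, unit=1, anchor="q3")
        _, idx_literal = winsorize_outliers(x, unit=1, anchor="q1")
        assert idx_default == [0] and set(idx_literal) == {0, 6}


class TestCohensD:
    @pytest.mark.parametrize(
        "m1,s1,n1,m2,s2,n2,expected",
        [
            (35.61, 8.1, 33, 24.94, 6.0, 31, -1.49),  # questionnaire
            (35.52, 6.4, 33, 10.35, 4.9, 31, -4.40),  # screening scale
            (33.70, 5.4, 33, 33.74, 6.3, 31, 0.01),  # age
            (9.42, 5.6, 24, 9.33, 5.1, 24, -0.02),  # habituation trials
        ],
    )
    def test_printed_effect_sizes_recomputed(self, m1, s1, n1, m2, s2, n2, expected):
        assert round(cohens_d_from_summary(m1, s1, n1, m2, s2, n2), 2) == expected

    def test_equal_means_give_zero(self):
        assert cohens_d_from_summary(5, 1, 10, 5, 2, 12) == 0.0

    def test_zero_pooled_spread_rejected(self):
        with pytest.raises(DegenerateInputError):
            cohens_d_from_summary(1, 0, 5, 2, 0, 5)


class TestOnewayAnova:
    def test_identical_samples_give_zero_f(self):
        x = np.random.default_rng(7).normal(size=30)
        comp = oneway_anova(x, x)
        assert comp.F_statistic == pytest.approx(0.0, abs=1e-12)
        assert comp.cohens_d == 0.0

    @given(
        st.lists(st.floats(-50, 50), min_size=4, max_size=30),
        st.lists(st.floats(-50, 50), min_size=4, max_size=30),
    )
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_f_equals_squared_t(self, a, b):
        x1, x2 = np.array(a), np.array(b)
        if np.ptp(x1) == 0 and np.ptp(x2) == 0:
            return
        comp = oneway_anova(x1, x2)
        t = sps.ttest_ind(x1, x2).statistic
        assert comp.F_statistic == pytest.approx(t**2, rel=1e-8, abs=1e-10)

    def test_double_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            oneway_anova([1.0, 1.0], [2.0, 2.0])


def mixed_anova_oracle(vals, labels):
    """Textbook mixed-design sums-of-squares partition, written directly."""
    vals = np.asarray(vals, float)
    labels = np.asarray(labels)
    n, k = vals.shape
    grand = vals.mean()
    groups = np.unique(labels)
    g = groups.size
    subj_means = vals.mean(axis=1)
    block_means_ = vals.mean(axis=0)
    ss_between_subj = k * np.sum((subj_means - grand) ** 2)
    ss_group = k * sum(
        (labels == gr).sum() * (vals[labels == gr].mean() - grand) ** 2 for gr in groups
    )
    ss_subj_within = ss_between_subj - ss_group
    ss_total = np.sum((vals - grand) ** 2)
    ss_within = ss_total - ss_between_subj
    ss_block = n * np.sum((block_means_ - grand) ** 2)
    ss_inter = 0.0
    for gr in groups:
        sub = vals[labels == gr]
        gmean = sub.mean()
        for j in range(k):
            ss_inter += sub.shape[0] * (sub[:, j].mean() - gmean - block_means_[j] + grand) ** 2
    ss_err = ss_within - ss_block - ss_inter
    f_group = (ss_group / (g - 1)) / (ss_subj_within / (n - g))
    f_block = (ss_block / (k - 1)) / (ss_err / ((n - g) * (k - 1)))
    f_inter = (ss_inter / ((g - 1) * (k - 1))) / (ss_err / ((n - g) * (k - 1)))
    return f_group, f_block, f_inter, (ss_total, ss_between_subj + ss_within)


class TestRmAnovaBlocks:
    def test_constant_data_gives_zero_f(self):
        vals = np.full((10, 3), 2.0)
        out = rm_anova_blocks(vals, ["a"] * 5 + ["b"] * 5)
        assert all(out[k]["F"] == 0.0 for k in out)

    def test_pure_block_effect_dominates_without_interaction(self):
        # additive block effect, identical groups, small noise: the block F
        # is huge, group and interaction Fs stay near their null size
        rng = np.random.default_rng(11)
        base = np.array([1.0, 2.0, 3.0])
        vals = np.tile(base, (12, 1)) + rng.normal(0, 0.05, (12, 3))
        out = rm_anova_blocks(vals, ["a"] * 6 + ["b"] * 6)
        assert out["block"]["F"] > 100
        assert out["interaction"]["F"] < 10
        assert out["group"]["F"] < 10

    def test_matches_textbook_sums_of_squares_on_random_data(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=(14, 3)) + np.array([0.0, 0.4, 0.9])
        labels = np.array(["a"] * 7 + ["b"] * 7)
        vals[labels == "b"] += 0.5
        out = rm_anova_blocks(vals, labels)
        f_group, f_block, f_inter, (ss_t, ss_parts) = mixed_anova_oracle(vals, labels)
        assert ss_t == pytest.approx(ss_parts, abs=1e-8)
        assert out["group"]["F"] == pytest.approx(f_group, rel=1e-6)
        assert out["block"]["F"] == pytest.approx(f_block, rel=1e-6)
        assert out["interaction"]["F"] == pytest.approx(f_inter, rel=1e-6)

    def test_missing_blocks_rejected(self):
        vals = np.ones((4, 3))
        vals[0, 1] = np.nan
        with pytest.raises(ParameterError):
            rm_anova_blocks(vals, ["a", "a", "b", "b"])


class TestCorrelations:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, p = correlations(x, x, "pearson")
        assert r == pytest.approx(1.0)

    def test_monotone_transform_spearman_one_pearson_below(self):
        x = np.linspace(0.1, 5, 50)
        y = np.exp(x)
        rs, _ = correlations(x, y, "spearman")
        rp, _ = correlations(x, y, "pearson")
        assert rs == pytest.approx(1.0)
        assert rp < 1.0

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            correlations([1, 1, 1], [1, 2, 3])


class TestBonferroni:
    @pytest.mark.parametrize(
        "m,reported", [(11, 0.0045), (4, 0.013), (1, 0.05), (5, 0.01)]
    )
    def test_reported_levels(self, m, reported):
        assert round_alpha(bonferroni_alpha(0.05, m)) == reported

    def test_corrected_level_times_m_is_alpha(self):
        for m in range(1, 30):
            assert bonferroni_alpha(0.05, m) * m == pytest.approx(0.05)

    def test_zero_comparisons_rejected(self):
        with pytest.raises(ParameterError):
            bonferroni_alpha(0.05, 0)
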