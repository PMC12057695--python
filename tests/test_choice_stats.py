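import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from berghia_social.choice_stats import (
    binomial_table,
    exact_binomial_test,
    log_latencies,
    welch_t_test,
    wilcoxon_one_sample,
)

from oracles import binomial_two_sided_pvalue, wilcoxon_exact_bruteforce


class TestExactBinomial:
    @pytest.mark.parametrize(
        "k, n, printed",
        [
            (23, 40, 0.43), (6, 15, 0.61), (9, 18, 1.00), (6, 24, 0.023),
            (13, 28, 0.85), (9, 22, 0.52), (10, 16, 0.45), (11, 28, 0.35),
            (8, 30, 0.016), (7, 17, 0.63),
        ],
    )
    def test_published_choice_assay_pvalues(self, k, n, printed):
        # one source value (11/28 -> 0.35) is rounded up one ulp from the
        # exact 0.3449; tolerance covers half an ulp plus that rounding
        res = exact_binomial_test(k, n, 0.5)
        assert res.p_value == pytest.approx(printed, abs=0.006)

    def test_no_successes_small_sample(self):
        res = exact_binomial_test(0, 5, 0.5)
        assert res.p_value == pytest.approx(0.0625)  # 2 * (1/2)^5
        assert res.ci_low == 0.0

    @settings(deadline=None, derandomize=True)
    @given(k=st.integers(0, 24))
    def test_symmetry_at_half(self, k):
        a = exact_binomial_test(k, 24, 0.5)
        b = exact_binomial_test(24 - k, 24, 0.5)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)

    @pytest.mark.parametrize("p_null", [0.5, 0.25, 0.7])
    @pytest.mark.parametrize("n", [5, 12, 20])
    def test_matches_direct_enumeration(self, n, p_null):
        for k in range(n + 1):
            expected = binomial_two_sided_pvalue(k, n, p_null)
            assert exact_binomial_test(k, n, p_null).p_value == pytest.approx(
                expected, rel=1e-9
            )

    def test_interval_brackets_the_proportion(self):
        for method in ("clopper-pearson", "jeffreys"):
            res = exact_binomial_test(6, 24, 0.5, ci_method=method)
            assert res.ci_low <= 6 / 24 <= res.ci_high

    def test_jeffreys_option_changes_interval_not_pvalue(self):
        cp = exact_binomial_test(6, 24, 0.5)
        jf = exact_binomial_test(6, 24, 0.5, ci_method="jeffreys")
        assert cp.p_value == jf.p_value
        assert (cp.ci_low, cp.ci_high) != (jf.ci_low, jf.ci_high)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            exact_binomial_test(5, 4)
        with pytest.raises(ValueError):
            exact_binomial_test(1, 4, p_null=0.0)


class TestWelch:
    def test_published_group_size_comparisons(self, three_day, seven_day):
        res = welch_t_test(three_day.mean_group_sizes, seven_day.mean_group_sizes)
        # printed columns give 0.1096/23.549; the source computed from
        # unrounded per-trial means (0.11074/23.553)
        assert res.t_stat == pytest.approx(0.10963, abs=1e-4)
        assert res.df == pytest.approx(23.549, abs=1e-2)
        res_max = welch_t_test(three_day.max_group_sizes, seven_day.max_group_sizes)
        assert res_max.t_stat == 0.0
        assert res_max.df == pytest.approx(25.201, abs=1e-2)
        assert res_max.p_value == 1.0

    def test_identical_samples(self):
        res = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_stat == 0.0 and res.p_value == 1.0

    def test_degenerate_constant_samples(self):
        res = welch_t_test([2.0, 2.0, 2.0], [2.0, 2.0])
        assert (res.t_stat, res.p_value) == (0.0, 1.0)

    def test_equal_variance_equal_n_limit_matches_pooled_t(self, rng):
        a = rng.normal(0, 1, 12)
        b = a + 0.3  # identical sample variance: Welch df collapses to 2n-2
        welch = welch_t_test(a, b)
        pooled = stats.ttest_ind(a, b, equal_var=True)
        assert welch.t_stat == pytest.approx(float(pooled.statistic), abs=1e-12)
        assert welch.p_value == pytest.approx(float(pooled.pvalue), abs=1e-12)

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0])


class TestSignedRank:
    def test_all_values_above_location_give_maximal_rank_sum(self, rng):
        # 21 values above the tested location: V = 21*22/2 = 231, the
        # published statistic for the home-tank proportions
        values = 0.5 + rng.uniform(0.01, 0.5, size=21)
        res = wilcoxon_one_sample(values, 0.5)
        assert res.statistic_V == 231.0
        assert res.z > 3.9
        assert res.effect_size_r == pytest.approx(res.z / np.sqrt(21))

    def test_symmetric_pairs_center_the_statistic(self):
        values = [0.5 + d for d in (0.1, -0.1, 0.2, -0.2, 0.3, -0.3)]
        res = wilcoxon_one_sample(values, 0.5)
        assert res.statistic_V == 6 * 7 / 4  # n(n+1)/4
        assert res.z == 0.0 and res.p_value == 1.0

    def test_all_at_location_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            wilcoxon_one_sample([0.5, 0.5], 0.5)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize("n", [5, 7, 8])
    def test_exact_method_matches_sign_flip_enumeration(self, n, seed):
        values = np.random.default_rng(seed).normal(0.6, 0.3, size=n)
        v_oracle, p_oracle = wilcoxon_exact_bruteforce(values, 0.5)
        res = wilcoxon_one_sample(values, 0.5, method="exact")
        assert res.statistic_V == v_oracle
        assert res.p_value == pytest.approx(p_oracle, rel=1e-12)

    def test_approximation_agrees_with_reference_implementation(self, rng):
        d = rng.normal(0.1, 1.0, size=40)
        res = wilcoxon_one_sample(d + 0.5, 0.5)
        ref = stats.wilcoxon(d, correction=True, method="approx")
        assert res.p_value == pytest.approx(float(ref.pvalue), rel=1e-9)

    def test_effect_size_bounded_by_one(self, rng):
        values = 0.5 + rng.uniform(0.01, 0.5, size=15)
        res = wilcoxon_one_sample(values, 0.5)
        assert abs(res.effect_size_r) <= 1.0

    def test_exact_requires_no_ties(self):
        with pytest.raises(ValueError, match="untied"):
            wilcoxon_one_sample([0.6, 0.6, 0.7], 0.5, method="exact")


class TestHelpers:
    def test_log_latencies(self):
        out = log_latencies([1.0, np.e])
        assert out == pytest.approx([0.0, 1.0])
        with pytest.raises(ValueError):
            log_latencies([0.0, 1.0])

    def test_binomial_table_over_packaged_records(self, choice_records):
        table = binomial_table(choice_records)
        assert len(table) == 10
        fc = table[(table.assay == "FC") & (table.acclimation == "ASW")].iloc[0]
        assert fc.p_value == pytest.approx(0.0227, abs=1e-3)
        assert (table.ci_low <= table.proportion_social).all()
        assert (table.proportion_social <= table.ci_high).all()
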