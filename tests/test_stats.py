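import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings, strategies as st

import tastecircuit as tc
from tastecircuit.stats import StatsInputError


class TestAnovaFromSummary:
    @pytest.mark.parametrize("variable,f_printed", [
        ("age_years", 0.75),
        ("body_mass_index", 30.42),
        ("drive_for_thinness", 127.73),
        ("trait_anxiety", 88.17),
        ("sensitivity_to_reward", 3.84),
    ])
    def test_published_behavioral_f_values(self, behavioral_targets, variable, f_printed):
        res = tc.anova_from_summary(behavioral_targets[variable])
        assert res.statistic == pytest.approx(f_printed, rel=0.02)

    def test_identical_group_means_give_zero_f(self):
        summary = tc.GroupSummary("v", [tc.GroupMoments(g, 5.0, 1.0, 20)
                                        for g in "abc"])
        res = tc.anova_from_summary(summary)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_zero_within_variance_flags_infinite_f(self):
        summary = tc.GroupSummary("v", [tc.GroupMoments("a", 1.0, 0.0, 10),
                                        tc.GroupMoments("b", 2.0, 0.0, 10)])
        res = tc.anova_from_summary(summary)
        assert np.isinf(res.statistic)
        assert res.extra["infinite_f"]

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_classical_anova_on_raw_vectors(self, seed):
        rng = np.random.default_rng(seed)
        values, groups = [], []
        for g in ("a", "b", "c"):
            n = int(rng.integers(3, 30))
            values.extend(rng.normal(rng.uniform(-1, 1), 1.0, n))
            groups.extend([g] * n)
        summary = tc.summary_from_values("v", values, groups)
        res = tc.anova_from_summary(summary)
        arrays = [np.asarray(values)[np.asarray(groups) == g] for g in "abc"]
        want = sps.f_oneway(*arrays)
        assert res.statistic == pytest.approx(want.statistic, abs=1e-9, rel=1e-9)
        assert res.p_value == pytest.approx(want.pvalue, abs=1e-9)


class TestAdjustedGroupModel:
    def test_without_covariates_reduces_to_oneway_anova(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=30)
        groups = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        res = tc.adjusted_group_model(values, groups)["group"]
        want = sps.f_oneway(values[:10], values[10:20], values[20:])
        assert res.statistic == pytest.approx(want.statistic, rel=1e-9)

    def test_covariate_effect_is_separated_from_group(self):
        rng = np.random.default_rng(2)
        n = 90
        groups = ["a", "b", "c"] * 30
        cov = pd.DataFrame({"med": rng.integers(0, 2, n).astype(float)})
        y = 2.0 * cov["med"].to_numpy() + rng.normal(size=n)
        out = tc.adjusted_group_model(y, groups, cov)
        assert out["med"].p_value < 1e-6
        assert out["group"].p_value > 0.01

    def test_group_shift_of_one_sd_is_detected_with_high_power(self):
        rng = np.random.default_rng(3)
        reps, hits = 400, 0
        groups = ["a"] * 25 + ["b"] * 25
        for _ in range(reps):
            y = np.concatenate([rng.normal(0, 1, 25), rng.normal(1, 1, 25)])
            hits += tc.adjusted_group_model(y, groups)["group"].p_value < 0.05
        assert hits / reps > 0.9

    def test_aliased_design_is_reported(self):
        groups = ["a"] * 5 + ["b"] * 5
        cov = pd.DataFrame({"dup": [0.0] * 5 + [1.0] * 5})  # identical to group
        with pytest.raises(StatsInputError, match="aliased"):
            tc.adjusted_group_model(np.arange(10.0), groups, cov)


class TestPairwisePosthoc:
    def test_two_groups_bonferroni_is_identity(self):
        rng = np.random.default_rng(4)
        res = tc.pairwise_posthoc(rng.normal(size=20), ["a"] * 10 + ["b"] * 10)
        assert len(res) == 1
        assert res[0].adjusted_p == pytest.approx(res[0].p_value)

    def test_three_groups_bonferroni_triples_p(self):
        rng = np.random.default_rng(5)
        res = tc.pairwise_posthoc(rng.normal(size=30), ["a", "b", "c"] * 10)
        for r in res:
            assert r.adjusted_p == pytest.approx(min(1.0, 3 * r.p_value))

    @pytest.mark.parametrize("method", ["bonferroni_welch", "dunnett_t3"])
    def test_familywise_error_controlled_under_null(self, method):
        rng = np.random.default_rng(6)
        reps, fw = 2000, 0
        for _ in range(reps):
            values = rng.normal(size=36)
            res = tc.pairwise_posthoc(values, ["a", "b", "c"] * 12, method)
            fw += any(r.adjusted_p < 0.05 for r in res)
        assert fw / reps <= 0.055

    def test_tiny_group_rejected(self):
        with pytest.raises(StatsInputError):
            tc.pairwise_posthoc([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestKruskalWallis:
    def test_hand_computed_h_without_ties(self):
        res = tc.kruskal_wallis([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert res.statistic == pytest.approx(27 / 7, abs=1e-9)

    def test_identical_groups_give_zero_h(self):
        res = tc.kruskal_wallis([2.0] * 8, ["a"] * 4 + ["b"] * 4)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_matches_exhaustive_rank_statistic(self):
        """Brute-force H from rank sums for every small dataset tried."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            n1, n2 = int(rng.integers(2, 5)), int(rng.integers(2, 5))
            values = rng.normal(size=n1 + n2)
            groups = ["a"] * n1 + ["b"] * n2
            res = tc.kruskal_wallis(values, groups)
            n = n1 + n2
            ranks = sps.rankdata(values)
            h = 12 / (n * (n + 1)) * (ranks[:n1].sum() ** 2 / n1
                                      + ranks[n1:].sum() ** 2 / n2) - 3 * (n + 1)
            assert res.statistic == pytest.approx(h, abs=1e-9)


class TestRegression:
    def test_perfect_line_gives_unit_correlation(self):
        x = np.arange(10.0)
        res = tc.brain_behavior_regression(x, 2 * x)
        assert res.extra["r"] == pytest.approx(1.0)
        assert res.statistic == pytest.approx(2.0)

    def test_negative_slope_gives_negative_r(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=50)
        res = tc.brain_behavior_regression(x, -x + 0.01 * rng.normal(size=50))
        assert res.extra["r"] < -0.99

    def test_null_rejection_rate_matches_critical_r(self):
        """For n=25, |r| > 0.396 should occur in ~5% of independent draws."""
        rng = np.random.default_rng(9)
        reps, hits = 2000, 0
        for _ in range(reps):
            res = tc.brain_behavior_regression(rng.normal(size=25), rng.normal(size=25))
            hits += abs(res.extra["r"]) > 0.396
        assert 0.03 < hits / reps < 0.07

    def test_constant_x_rejected(self):
        with pytest.raises(StatsInputError):
            tc.brain_behavior_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert tc.benjamini_hochberg([0.2]) == [0.2]

    def test_hand_computed_step_up_values(self):
        assert tc.benjamini_hochberg([0.01, 0.02, 0.03, 0.04]) == \
            pytest.approx([0.04, 0.04, 0.04, 0.04])
        assert tc.benjamini_hochberg([0.001, 0.5]) == pytest.approx([0.002, 0.5])

    def test_out_of_range_rejected(self):
        with pytest.raises(StatsInputError):
            tc.benjamini_hochberg([0.1, 1.5])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=25),
           st.integers(0, 2**31 - 1))
    def test_permutation_equivariance_and_dominance(self, ps, seed):
        adj = tc.benjamini_hochberg(ps)
        assert all(0 <= a <= 1 for a in adj)
        assert all(a >= p - 1e-15 for a, p in zip(adj, ps))
        perm = np.random.default_rng(seed).permutation(len(ps))
        adj_perm = tc.benjamini_hochberg([ps[i] for i in perm])
        assert adj_perm == pytest.approx([adj[i] for i in perm])
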