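import math

import numpy as np
import pytest
from scipy import stats as sps

from stratperm import (
    PermutationConfig,
    StratificationPlan,
    exact_test_small,
    permutation_test,
    permute_within_strata,
    stratify_by_quantiles,
)
from stratperm.errors import InfeasibleStrataError, StateSpaceError, WeightingError

from conftest import make_table, random_table


def mc_bound(p_exact, B, k=3):
    return k * math.sqrt(p_exact * (1 - p_exact) / B)


class TestPermuteWithinStrata:
    def test_singleton_stratum_never_changes(self, rng):
        plan = StratificationPlan(2, [0.5], [0, 1, 1, 1])
        resp = np.array([1, 0, 1, 0])
        for _ in range(50):
            out = permute_within_strata(resp, plan, rng=rng)
            assert out[0] == 1  # the lone stratum-0 site keeps its label
            assert out.sum() == 2

    def test_uniform_marginal_frequencies(self, rng):
        """One occupied label among 4 sites: each site occupied ~1/4."""
        plan = StratificationPlan(1, [], [0, 0, 0, 0])
        resp = np.array([1, 0, 0, 0])
        B = 40_000
        counts = np.zeros(4)
        for _ in range(B):
            counts += permute_within_strata(resp, plan, rng=rng)
        freq = counts / B
        se = math.sqrt(0.25 * 0.75 / B)
        assert np.all(np.abs(freq - 0.25) < 3 * se)

    def test_weighted_single_draw_probability(self, rng):
        """Weights [3, 1] for one label: first site chosen with p = 3/4."""
        plan = StratificationPlan(1, [], [0, 0])
        resp = np.array([1, 0])
        w = np.array([3.0, 1.0])
        B = 40_000
        hits = sum(permute_within_strata(resp, plan, weights=w, rng=rng)[0] for _ in range(B))
        se = math.sqrt(0.75 * 0.25 / B)
        assert abs(hits / B - 0.75) < 3 * se

    def test_counts_conserved_per_stratum(self, rng):
        table = random_table(rng, 60)
        plan = stratify_by_quantiles(table, 3)
        resp = table.response
        for _ in range(200):
            out = permute_within_strata(resp, plan, rng=rng)
            for idx in plan.stratum_indices():
                assert out[idx].sum() == resp[idx].sum()

    def test_zero_weight_everywhere_is_error(self):
        plan = StratificationPlan(1, [], [0, 0, 0])
        with pytest.raises(WeightingError):
            permute_within_strata(
                np.array([1, 0, 0]), plan, weights=np.zeros(3),
                rng=np.random.default_rng(0),
            )


class TestExactOracle:
    def test_worked_toy_exact_third(self, toy_table, toy_plan):
        """[0,0,1,1] vs stressor [1,1,0,0]: 2 of C(4,2)=6 placements reach |T|=1."""
        cfg = PermutationConfig(statistic="mean_difference", n_permutations=10, seed=0)
        res = exact_test_small(toy_table, toy_plan, cfg)
        assert res.observed == pytest.approx(-1.0)
        assert res.p_value == pytest.approx(1 / 3, abs=1e-12)

    def test_two_aligned_strata_enumeration(self):
        """Two strata, each 1 occupied of 2 sites, stressor aligned with
        occupancy: the 4 equally likely states give T in {1, 0, 0, -1},
        so p(|T| >= 1) = 1/2."""
        table = make_table([1, 0, 1, 0], [1.0, 0, 1, 0], [0.2, 0.2, 0.8, 0.8])
        plan = StratificationPlan(2, [0.5], [0, 0, 1, 1])
        cfg = PermutationConfig(statistic="mean_difference")
        res = exact_test_small(table, plan, cfg)
        assert res.observed == pytest.approx(1.0)
        assert res.p_value == pytest.approx(0.5, abs=1e-12)

    def test_weighted_uniform_weights_equals_unweighted(self, rng):
        table = random_table(rng, 12)
        plan = stratify_by_quantiles(table, 2)
        cfg_u = PermutationConfig(statistic="mean_difference")
        cfg_w = PermutationConfig(statistic="mean_difference", weighted_permutation=True)
        p_u = exact_test_small(table, plan, cfg_u).p_value
        p_w = exact_test_small(
            table, plan, cfg_w, permutation_weights=np.ones(table.n_sites)
        ).p_value
        assert p_w == pytest.approx(p_u, abs=1e-12)

    def test_state_space_cap_refuses(self, rng):
        table = random_table(rng, 200)
        plan = stratify_by_quantiles(table, 2)
        with pytest.raises(StateSpaceError, match="Monte-Carlo"):
            exact_test_small(table, plan, PermutationConfig())

    def test_exact_probabilities_sum_to_one(self, rng):
        table = random_table(rng, 14, continuous=True)
        plan = stratify_by_quantiles(table, 2)
        cfg = PermutationConfig(statistic="point_biserial", weighted_permutation=True, log1p=True)
        res = exact_test_small(table, plan, cfg)
        assert res.null_probabilities.sum() == pytest.approx(1.0, abs=1e-9)


class TestPermutationTest:
    def test_monte_carlo_converges_to_exact(self, toy_table, toy_plan):
        cfg = PermutationConfig(n_permutations=10_000, seed=99)
        p_mc = permutation_test(toy_table, toy_plan, cfg).p_value
        assert abs(p_mc - 1 / 3) <= mc_bound(1 / 3, 10_000)

    def test_degenerate_labels_give_p_one(self):
        table = make_table([1, 1, 1, 1], [1.0, 0, 1, 0], [0.1, 0.2, 0.8, 0.9])
        plan = StratificationPlan(2, [0.5], [0, 0, 1, 1])
        res = permutation_test(table, plan, PermutationConfig(n_permutations=500, seed=1))
        assert res.observed == 0.0
        assert res.p_value == 1.0

    def test_all_strata_infeasible_refused(self):
        table = make_table([0, 1, 0, 1], [0.0, 0, 0, 0], [0.1, 0.2, 0.8, 0.9])
        plan = StratificationPlan(2, [0.5], [0, 0, 1, 1])
        with pytest.raises(InfeasibleStrataError) as exc:
            permutation_test(table, plan, PermutationConfig(n_permutations=10))
        assert exc.value.report is not None
        assert exc.value.report.all_infeasible

    def test_seed_reproducibility(self, rng):
        table = random_table(rng, 80)
        plan = stratify_by_quantiles(table, 4)
        cfg = PermutationConfig(n_permutations=2000, seed=7)
        a = permutation_test(table, plan, cfg)
        b = permutation_test(table, plan, cfg)
        np.testing.assert_array_equal(a.null_draws, b.null_draws)
        assert a.p_value == b.p_value

    def test_p_invariant_to_stressor_sign_convention(self, rng):
        """Two-sidedness: recoding which group is 'exposed' flips the sign
        of the statistic but not the p-value."""
        table = random_table(rng, 60)
        plan = stratify_by_quantiles(table, 2)
        cfg = PermutationConfig(n_permutations=4000, seed=5)
        p1 = permutation_test(table, plan, cfg)
        flipped = make_table(
            table.response, 1.0 - table.stressor, table.suitability
        )
        p2 = permutation_test(flipped, plan, cfg)
        assert p1.observed == pytest.approx(-p2.observed)
        assert p1.p_value == p2.p_value

    def test_add_one_rule(self, toy_table, toy_plan):
        cfg = PermutationConfig(n_permutations=100, seed=2, p_value_rule="add_one")
        res = permutation_test(toy_table, toy_plan, cfg)
        n_extreme = int((np.abs(res.null_draws) >= abs(res.observed) - 1e-12).sum())
        assert res.p_value == pytest.approx((n_extreme + 1) / 101)

    def test_equal_weights_reproduce_unweighted_null(self, rng):
        table = random_table(rng, 200)
        plan = stratify_by_quantiles(table, 4)
        r_u = permutation_test(table, plan, PermutationConfig(n_permutations=5000, seed=21))
        r_w = permutation_test(
            table, plan,
            PermutationConfig(n_permutations=5000, seed=22, weighted_permutation=True),
            permutation_weights=np.ones(table.n_sites),
        )
        assert sps.ks_2samp(r_u.null_draws, r_w.null_draws).pvalue > 0.01

    def test_observed_equals_aggregated_per_stratum(self, rng):
        from stratperm import aggregate_strata

        table = random_table(rng, 100, continuous=True)
        plan = stratify_by_quantiles(table, 4)
        cfg = PermutationConfig(statistic="point_biserial", log1p=True, n_permutations=10)
        res = permutation_test(table, plan, cfg)
        assert res.observed == pytest.approx(
            aggregate_strata(res.per_stratum_observed, res.per_stratum_defined, "mean")
        )
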