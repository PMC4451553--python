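import math

import numpy as np
import pytest

from stratperm import (
    AllocationProblem,
    ComplexSpec,
    PermutationConfig,
    allocation_search,
    apply_allocation,
    enumerate_compositions,
    observed_statistic,
    problem_from_table,
    random_composition,
    sensitivity_report,
    stratify_by_quantiles,
)
from stratperm.errors import AllocationError

from conftest import make_table, random_table


def meadow_like(rng, n=60, with_complex=True):
    table = random_table(rng, n, p_resp=0.3, p_stress=0.4, continuous=True)
    if with_complex:
        cid = np.array([None] * n, dtype=object)
        cid[:2] = "cx_a"
        cid[2:5] = "cx_b"
        table.data["complex_id"] = cid
        # put the complex totals on the increment grid so the baseline
        # allocation is itself a reachable composition
        table.data.loc[0, "stressor"] = 30.0
        table.data.loc[1, "stressor"] = 70.0
        table.data.loc[2, "stressor"] = 50.0
        table.data.loc[3, "stressor"] = 50.0
        table.data.loc[4, "stressor"] = 0.0
    return table


class TestCompositions:
    def test_three_member_count_is_stars_and_bars(self):
        comps = enumerate_compositions(10, 3)
        assert len(comps) == math.comb(12, 2) == 66
        assert len(set(comps)) == 66
        assert all(sum(c) == 10 for c in comps)

    def test_random_composition_uniform(self, rng):
        comps = [random_composition(10, 2, rng) for _ in range(20_000)]
        assert all(sum(c) == 10 for c in comps)
        counts = np.bincount([c[0] for c in comps], minlength=11)
        # 11 equally likely compositions
        expected = 20_000 / 11
        assert np.all(np.abs(counts - expected) < 5 * math.sqrt(expected))


class TestApplyAllocation:
    def test_direct_product(self, rng):
        table = meadow_like(rng)
        problem = problem_from_table(table)
        out = apply_allocation(table, problem, {"cx_a": (3, 7), "cx_b": (10, 0, 0)})
        assert out.stressor[0] == pytest.approx(30.0)
        assert out.stressor[1] == pytest.approx(70.0)
        assert out.stressor[2] == pytest.approx(100.0)
        assert out.stressor[3] == 0.0
        # non-members untouched
        np.testing.assert_array_equal(out.stressor[5:], table.stressor[5:])

    def test_bad_composition_rejected(self, rng):
        table = meadow_like(rng)
        problem = problem_from_table(table)
        with pytest.raises(AllocationError):
            apply_allocation(table, problem, {"cx_a": (3, 6), "cx_b": (10, 0, 0)})

    def test_total_conserved_to_machine_precision(self, rng):
        table = meadow_like(rng)
        problem = problem_from_table(table)
        for comp_a in enumerate_compositions(10, 2):
            out = apply_allocation(table, problem, {"cx_a": comp_a, "cx_b": (5, 3, 2)})
            assert out.stressor[:2].sum() == pytest.approx(100.0, rel=1e-15)
            assert out.stressor[2:5].sum() == pytest.approx(100.0, rel=1e-15)


class TestAllocationSearch:
    def setup_search(self, rng, **kwargs):
        table = meadow_like(rng)
        problem = problem_from_table(table, n_iterations=kwargs.pop("n_iterations", 10_000))
        plan = stratify_by_quantiles(table, 2)
        cfg = PermutationConfig(statistic="point_biserial", log1p=True, n_permutations=200)
        return table, problem, plan, cfg

    def test_random_matches_exhaustive_extremes(self, rng):
        table, problem, plan, cfg = self.setup_search(rng)
        ex = allocation_search(table, problem, plan, cfg, method="exhaustive")
        ra = allocation_search(
            table, problem, plan, cfg, method="random", rng=np.random.default_rng(4)
        )
        assert ra.min_value == pytest.approx(ex.min_value, abs=1e-12)
        assert ra.max_value == pytest.approx(ex.max_value, abs=1e-12)
        assert ex.exact and not ra.exact

    def test_extremes_bracket_baseline(self, rng):
        table, problem, plan, cfg = self.setup_search(rng)
        res = allocation_search(table, problem, plan, cfg, method="exhaustive")
        baseline, _ = observed_statistic(table, plan, cfg)
        assert res.min_value <= baseline + 1e-12
        assert res.max_value >= baseline - 1e-12

    def test_single_member_complexes_have_no_freedom(self, rng):
        table = random_table(rng, 30, continuous=True)
        table.data["complex_id"] = [None] * 28 + ["c1", "c2"]
        problem = problem_from_table(table)
        plan = stratify_by_quantiles(table, 2)
        cfg = PermutationConfig(statistic="point_biserial", log1p=True)
        res = allocation_search(table, problem, plan, cfg)
        baseline, _ = observed_statistic(table, plan, cfg)
        assert res.min_value == pytest.approx(baseline)
        assert res.max_value == pytest.approx(baseline)

    def test_no_complexes_warns_and_returns_input(self, rng):
        table = random_table(rng, 30, continuous=True)
        problem = AllocationProblem(complexes={})
        plan = stratify_by_quantiles(table, 2)
        cfg = PermutationConfig(statistic="point_biserial", log1p=True)
        with pytest.warns(UserWarning):
            res = allocation_search(table, problem, plan, cfg)
        assert res.min_value == res.max_value

    def test_deterministic_under_seed(self, rng):
        table, problem, plan, cfg = self.setup_search(rng, n_iterations=2000)
        a = allocation_search(table, problem, plan, cfg, method="random",
                              rng=np.random.default_rng(11))
        b = allocation_search(table, problem, plan, cfg, method="random",
                              rng=np.random.default_rng(11))
        assert a.min_value == b.min_value and a.max_value == b.max_value
        np.testing.assert_array_equal(a.min_table.stressor, b.min_table.stressor)


class TestSensitivityReport:
    def test_concentrated_stressor_brackets_baseline(self, rng):
        """A complex holding the only stressor-positive sites: moving the
        total between an occupied and an unoccupied member must swing the
        statistic around the baseline."""
        n = 24
        resp = np.zeros(n, int)
        resp[:6] = 1
        suit = np.linspace(0.05, 0.95, n)
        stress = np.zeros(n)
        stress[0] = 50.0  # occupied member
        stress[12] = 50.0  # unoccupied member
        stress[7] = 5.0  # fixed use outside the complex keeps the statistic defined
        table = make_table(resp, stress, suit)
        table.data["complex_id"] = ["cx"] * 2 + [None] * (n - 2)
        table.data.loc[1, "complex_id"] = None
        table.data.loc[12, "complex_id"] = "cx"

        problem = problem_from_table(table)
        plan = stratify_by_quantiles(table, 2)
        cfg = PermutationConfig(statistic="point_biserial", log1p=True, n_permutations=500, seed=9)
        search = allocation_search(table, problem, plan, cfg, method="exhaustive")
        baseline, _ = observed_statistic(table, plan, cfg)
        assert search.min_value < baseline < search.max_value

        res_min, res_max = sensitivity_report(search, plan, cfg)
        assert res_min.observed == pytest.approx(search.min_value)
        assert res_max.observed == pytest.approx(search.max_value)

    def test_eight_complex_uncertainty_run_end_to_end(self, rng):
        """Eight complexes of 3 members (24 uncertain sites) run end-to-end."""
        table = random_table(rng, 200, p_resp=0.15, p_stress=0.2, continuous=True)
        cid = np.array([None] * 200, dtype=object)
        for c in range(8):
            cid[c * 3: c * 3 + 3] = f"cx{c}"
        table.data["complex_id"] = cid
        problem = problem_from_table(table, n_iterations=500)
        assert sum(len(s.members) for s in problem.complexes.values()) == 24
        plan = stratify_by_quantiles(table, 4)
        cfg = PermutationConfig(statistic="point_biserial", log1p=True, n_permutations=300, seed=3)
        search = allocation_search(table, problem, plan, cfg, method="random",
                                   rng=np.random.default_rng(5))
        res_min, res_max = sensitivity_report(search, plan, cfg)
        assert 0 <= res_min.p_value <= 1 and 0 <= res_max.p_value <= 1
        assert search.min_value <= search.max_value
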