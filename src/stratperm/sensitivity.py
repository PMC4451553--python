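"""Allocation-uncertainty sensitivity analysis.

Reported stressor totals (e.g. stock nights recorded under one meadow name)
are sometimes shared by a *complex* of mapped polygons, and how the total is
split among members is uncertain.  This module redistributes each complex's
total among its members in fixed increments (default 10%, i.e. compositions
of 10 units), searches for the allocations that minimise and maximise the
observed aggregated association, and reruns the permutation test on those
two extreme datasets to see how fragile the baseline conclusion is.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .datatypes import PermutationConfig, SiteTable, StratificationPlan
from .errors import AllocationError, ParameterError
from .permute import observed_statistic, permutation_test
from .stats import aggregate_strata, log1_transform, stat_mean_difference, stat_point_biserial

logger = logging.getLogger("stratperm")

ENUMERATION_CAP = 10**5


@dataclass
class ComplexSpec:
    members: list[str]
    total_use: float


@dataclass
class AllocationProblem:
    """Complexes of sites sharing one reported stressor total.

    An allocation assigns each complex a composition: a split of
    ``round(1/increment)`` increment-units among its members, summing to
    100% of the complex total.
    """

    complexes: dict[str, ComplexSpec]
    increment: float = 0.10
    n_iterations: int = 100_000

    def __post_init__(self):
        if not (0 < self.increment <= 1):
            raise ParameterError("increment must be in (0, 1]")
        u = round(1.0 / self.increment)
        if abs(u * self.increment - 1.0) > 1e-9:
            raise ParameterError("increment must divide 1 evenly")
        seen: set[str] = set()
        for cid, spec in self.complexes.items():
            if spec.total_use < 0:
                raise ParameterError(f"complex {cid}: negative total_use")
            if not spec.members:
                raise ParameterError(f"complex {cid}: no members")
            overlap = seen & set(spec.members)
            if overlap:
                raise ParameterError(f"sites {sorted(overlap)} in more than one complex")
            seen |= set(spec.members)

    @property
    def n_units(self) -> int:
        return round(1.0 / self.increment)

    def composition_counts(self) -> dict[str, int]:
        u = self.n_units
        return {
            cid: math.comb(u + len(spec.members) - 1, len(spec.members) - 1)
            for cid, spec in self.complexes.items()
        }

    def total_space(self) -> int:
        out = 1
        for c in self.composition_counts().values():
            out *= c
        return out


def enumerate_compositions(n_units: int, n_parts: int) -> list[tuple[int, ...]]:
    """All splits of ``n_units`` indistinguishable units into ``n_parts``
    ordered non-negative parts (stars and bars)."""
    if n_parts == 1:
        return [(n_units,)]
    out = []
    for first in range(n_units + 1):
        for rest in enumerate_compositions(n_units - first, n_parts - 1):
            out.append((first, *rest))
    return out


def random_composition(n_units: int, n_parts: int, rng: np.random.Generator) -> tuple[int, ...]:
    """One composition uniform over the discrete simplex, via uniformly
    random bar placement among the n_units + n_parts - 1 slots."""
    if n_parts == 1:
        return (n_units,)
    bars = np.sort(rng.choice(n_units + n_parts - 1, size=n_parts - 1, replace=False))
    parts = np.diff(np.concatenate([[-1], bars, [n_units + n_parts - 1]])) - 1
    return tuple(int(v) for v in parts)


def apply_allocation(
    table: SiteTable,
    problem: AllocationProblem,
    allocation: dict[str, tuple[int, ...]],
) -> SiteTable:
    """Return a copy of the table with member stressor values replaced by
    share x total_use; non-member sites untouched."""
    u = problem.n_units
    out = table.copy()
    sid_to_row = {sid: i for i, sid in enumerate(out.site_id)}
    stressor = out.data["stressor"].to_numpy(dtype=float).copy()
    for cid, spec in problem.complexes.items():
        comp = allocation[cid]
        if len(comp) != len(spec.members):
            raise AllocationError(f"complex {cid}: composition has wrong length")
        if any(p < 0 or p != int(p) for p in comp) or sum(comp) != u:
            raise AllocationError(
                f"complex {cid}: composition {comp} is not {u} increment-units summing to 100%"
            )
        for sid, part in zip(spec.members, comp):
            if sid not in sid_to_row:
                raise AllocationError(f"complex {cid}: member {sid!r} not in table")
            stressor[sid_to_row[sid]] = (part / u) * spec.total_use
    out.data["stressor"] = stressor
    return out


@dataclass
class SearchResult:
    min_table: SiteTable
    max_table: SiteTable
    min_value: float
    max_value: float
    min_allocation: dict[str, tuple[int, ...]]
    max_allocation: dict[str, tuple[int, ...]]
    exact: bool
    n_evaluated: int
    baseline_value: float = field(default=float("nan"))


def _objective_factory(table, plan, config, aggregation_weights):
    """Fast observed-statistic evaluator that recomputes only the strata
    touched by complex members."""
    from .permute import _aggregation_weights

    x0 = table.stressor.copy()
    response = table.response
    labels = plan.labels
    K = plan.n_strata
    idx_by_stratum = plan.stratum_indices()
    agg_w = _aggregation_weights(config, plan, aggregation_weights)

    def stratum_value(k, x):
        idx = idx_by_stratum[k]
        if config.statistic == "mean_difference":
            s = stat_mean_difference(response[idx], x[idx] > 0, stratum=k)
        else:
            s = stat_point_biserial(response[idx], x[idx], stratum=k)
        return s.value if s.defined else 0.0, s.defined

    def evaluate(stressor_raw):
        x = log1_transform(stressor_raw) if config.log1p else stressor_raw
        vals = np.empty(K)
        defined = np.empty(K, dtype=bool)
        for k in range(K):
            vals[k], defined[k] = stratum_value(k, x)
        return aggregate_strata(vals, defined, config.aggregation, agg_w)

    return evaluate, x0, labels


def allocation_search(
    table: SiteTable,
    problem: AllocationProblem,
    plan: StratificationPlan,
    config: PermutationConfig,
    rng: np.random.Generator | None = None,
    aggregation_weights: np.ndarray | None = None,
    enumeration_cap: int = ENUMERATION_CAP,
    method: str = "auto",
) -> SearchResult:
    """Find allocations minimising / maximising the observed statistic.

    ``method='auto'`` enumerates the full composition space exhaustively
    when it has at most ``enumeration_cap`` states and otherwise draws
    ``problem.n_iterations`` random allocations (independently uniform per
    complex).  ``'random'`` / ``'exhaustive'`` force either mode.
    """
    rng = rng or np.random.default_rng()
    baseline, _ = observed_statistic(table, plan, config, aggregation_weights)

    if not problem.complexes:
        warnings.warn("no complexes to search; returning the input table", UserWarning)
        return SearchResult(table, table, baseline, baseline, {}, {}, True, 0, baseline)

    space = problem.total_space()
    if method == "auto":
        method = "exhaustive" if space <= enumeration_cap else "random"
    if method == "exhaustive" and space > enumeration_cap:
        raise ParameterError(f"composition space {space} exceeds cap {enumeration_cap}")

    evaluate, x0, _ = _objective_factory(table, plan, config, aggregation_weights)
    u = problem.n_units
    cids = list(problem.complexes)
    sid_to_row = {sid: i for i, sid in enumerate(table.site_id)}
    member_rows = {
        cid: np.array([sid_to_row[s] for s in problem.complexes[cid].members])
        for cid in cids
    }
    totals = {cid: problem.complexes[cid].total_use for cid in cids}

    def value_of(alloc: dict[str, tuple[int, ...]]) -> float:
        x = x0.copy()
        for cid in cids:
            x[member_rows[cid]] = (np.asarray(alloc[cid]) / u) * totals[cid]
        return evaluate(x)

    best_min = (math.inf, None)
    best_max = (-math.inf, None)
    n_eval = 0

    if method == "exhaustive":
        per_complex = [enumerate_compositions(u, len(problem.complexes[cid].members)) for cid in cids]
        for combo in product(*per_complex):
            alloc = dict(zip(cids, combo))
            v = value_of(alloc)
            n_eval += 1
            if v < best_min[0]:
                best_min = (v, alloc)
            if v > best_max[0]:
                best_max = (v, alloc)
    else:
        for _ in range(problem.n_iterations):
            alloc = {
                cid: random_composition(u, len(problem.complexes[cid].members), rng)
                for cid in cids
            }
            v = value_of(alloc)
            n_eval += 1
            if v < best_min[0]:
                best_min = (v, alloc)
            if v > best_max[0]:
                best_max = (v, alloc)

    min_table = apply_allocation(table, problem, best_min[1])
    max_table = apply_allocation(table, problem, best_max[1])
    logger.info(
        "allocation search (%s, %d evaluations): min=%.6g max=%.6g baseline=%.6g",
        method, n_eval, best_min[0], best_max[0], baseline,
    )
    return SearchResult(
        min_table=min_table,
        max_table=max_table,
        min_value=best_min[0],
        max_value=best_max[0],
        min_allocation=best_min[1],
        max_allocation=best_max[1],
        exact=(method == "exhaustive"),
        n_evaluated=n_eval,
        baseline_value=baseline,
    )


def sensitivity_report(
    search: SearchResult,
    plan: StratificationPlan,
    config: PermutationConfig,
    aggregation_weights: np.ndarray | None = None,
):
    """Rerun the permutation test on the two extreme allocations.

    Returns (result_min, result_max): how rare the observed association
    would be under the least and most favourable resolutions of the
    allocation uncertainty.
    """
    res_min = permutation_test(search.min_table, plan, config, aggregation_weights=aggregation_weights)
    res_max = permutation_test(search.max_table, plan, config, aggregation_weights=aggregation_weights)
    return res_min, res_max


def problem_from_table(
    table: SiteTable, totals: dict[str, float] | None = None, **kwargs
) -> AllocationProblem:
    """Build an AllocationProblem from the table's complex_id column.

    Complex totals default to the current sum of member stressor values, so
    the baseline allocation is itself a valid point of the search space
    whenever those sums are on the increment grid.
    """
    cids = table.complex_id
    if cids is None:
        raise ParameterError("table has no complex_id column")
    complexes: dict[str, ComplexSpec] = {}
    stressor = table.stressor
    sid = table.site_id
    mask = ~(np.asarray([c is None or (isinstance(c, float) and math.isnan(c)) for c in cids]))
    for cid in dict.fromkeys(cids[mask]):
        rows = np.flatnonzero(cids == cid)
        total = totals[cid] if totals else float(stressor[rows].sum())
        complexes[str(cid)] = ComplexSpec(members=[str(s) for s in sid[rows]], total_use=total)
    return AllocationProblem(complexes=complexes, **kwargs)
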