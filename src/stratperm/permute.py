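"""Stratified permutation null and two-sided Monte-Carlo p-value.

The null model: within each suitability stratum the occupied labels are
re-assigned at random — uniformly over arrangements, or, in weighted mode,
by successive sampling without replacement with selection probability
proportional to each site's predicted suitability (so that residual
within-stratum suitability variation is absorbed into the null).  Strata are
permuted independently and the per-stratum occupied counts are preserved
exactly in every draw.

Both stratum statistics are linear in the occupancy indicator once the
stressor and group sizes are fixed, so each permuted aggregate reduces to a
sum of per-site contributions over the selected sites.  Draws are generated
in a vectorised batch per stratum: uniform arrangements select the m
smallest of n iid uniform keys; weighted arrangements select the m smallest
of Exp(1)/w_i keys, which is distributionally identical to successive
weighted sampling without replacement (Efraimidis & Spirakis, 2006).

An exhaustive-enumeration oracle (:func:`exact_test_small`) computes the
exact null for small strata and serves as the reference the Monte-Carlo
engine is validated against.
"""

from __future__ import annotations

import logging
import math
from itertools import combinations

import numpy as np

from .datatypes import (
    PermutationConfig,
    PermutationResult,
    SiteTable,
    StratificationPlan,
)
from .errors import (
    InfeasibleStrataError,
    ParameterError,
    StateSpaceError,
    WeightingError,
)
from .stats import (
    StratumStatistic,
    aggregate_strata,
    log1_transform,
    stat_mean_difference,
    stat_point_biserial,
)
from .stratify import check_stratum_feasibility

logger = logging.getLogger("stratperm")

# ties at |T_b| == |T_obs| count as extreme; the epsilon guards against the
# scalar and vectorised code paths differing in the last ulp
_TIE_EPS = 1e-12

EXACT_STATE_CAP = 10**6


# ---------------------------------------------------------------------------
# linear representation of the stratum statistic
# ---------------------------------------------------------------------------

def _linear_form(statistic: str, x: np.ndarray, m: int):
    """Return (c, a, defined) with stratum statistic = a + sum(c[selected]).

    ``x`` is the stressor vector of the stratum, ``m`` the number of occupied
    labels the stratum must receive.  Both statistics are linear in the 0/1
    occupancy vector because all other moments are permutation-invariant.
    """
    n = len(x)
    if statistic == "mean_difference":
        pos = x > 0
        n1 = int(pos.sum())
        n0 = n - n1
        if n1 == 0 or n0 == 0:
            return None, 0.0, False
        c = np.where(pos, 1.0 / n1, -1.0 / n0)
        return c, 0.0, True
    if statistic == "point_biserial":
        pbar = m / n
        sp = math.sqrt(pbar * (1.0 - pbar))
        sx = float(np.std(x))
        if sp == 0.0 or sx == 0.0:
            return None, 0.0, False
        c = x / (n * sp * sx)
        a = -pbar * float(np.mean(x)) / (sp * sx)
        return c, a, True
    raise ParameterError(f"unknown statistic {statistic!r}")


def _observed_stratum_stats(
    response: np.ndarray, x: np.ndarray, plan: StratificationPlan, statistic: str
) -> list[StratumStatistic]:
    out = []
    for k, idx in enumerate(plan.stratum_indices()):
        if statistic == "mean_difference":
            out.append(stat_mean_difference(response[idx], x[idx] > 0, stratum=k))
        else:
            out.append(stat_point_biserial(response[idx], x[idx], stratum=k))
    return out


def observed_statistic(
    table: SiteTable,
    plan: StratificationPlan,
    config: PermutationConfig,
    aggregation_weights: np.ndarray | None = None,
) -> tuple[float, list[StratumStatistic]]:
    """Aggregated observed statistic plus the per-stratum pieces."""
    x = table.stressor
    if config.log1p:
        x = log1_transform(x)
    stats = _observed_stratum_stats(table.response, x, plan, config.statistic)
    values = np.array([s.value for s in stats])
    defined = np.array([s.defined for s in stats])
    weights = _aggregation_weights(config, plan, aggregation_weights)
    T = aggregate_strata(values, defined, config.aggregation, weights)
    return T, stats


def _aggregation_weights(config, plan, aggregation_weights):
    if config.aggregation != "weighted_mean":
        return None
    if aggregation_weights is not None:
        return np.asarray(aggregation_weights, dtype=float)
    return plan.stratum_sizes().astype(float)  # default: weight strata by size


# ---------------------------------------------------------------------------
# drawing permutations
# ---------------------------------------------------------------------------

def _check_weights(w: np.ndarray, m: int, stratum: int) -> None:
    if np.any(w < 0):
        raise WeightingError(f"negative suitability weight in stratum {stratum}")
    if m > 0 and int((w > 0).sum()) < m:
        raise WeightingError(
            f"stratum {stratum} must receive {m} occupied labels but has "
            f"only {int((w > 0).sum())} positive-weight sites"
        )


def _selection_keys(B: int, n: int, w: np.ndarray | None, rng: np.random.Generator) -> np.ndarray:
    """Keys whose m smallest entries mark the selected sites."""
    if w is None:
        return rng.random((B, n))
    with np.errstate(divide="ignore"):
        return rng.exponential(size=(B, n)) / w


def permute_within_strata(
    response: np.ndarray,
    plan: StratificationPlan,
    weights: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One permutation draw: re-assign occupied labels within each stratum.

    Unweighted: every arrangement of the stratum's m occupied labels is
    equally likely.  Weighted: labels are assigned by successive sampling
    without replacement with probability proportional to ``weights``.
    Per-stratum occupied counts are preserved exactly.
    """
    rng = rng or np.random.default_rng()
    response = np.asarray(response, dtype=np.int64)
    out = np.zeros_like(response)
    for k, idx in enumerate(plan.stratum_indices()):
        m = int(response[idx].sum())
        if m == 0:
            continue
        w = None
        if weights is not None:
            w = np.asarray(weights, dtype=float)[idx]
            _check_weights(w, m, k)
        keys = _selection_keys(1, len(idx), w, rng)[0]
        sel = np.argpartition(keys, m - 1)[:m] if m < len(idx) else np.arange(len(idx))
        out[idx[sel]] = 1
    assert int(out.sum()) == int(response.sum())
    return out


def _null_draws(
    response: np.ndarray,
    x: np.ndarray,
    plan: StratificationPlan,
    config: PermutationConfig,
    B: int,
    rng: np.random.Generator,
    perm_weights: np.ndarray | None,
    agg_weights: np.ndarray | None,
) -> np.ndarray:
    """B aggregated statistics under the within-stratum null, vectorised."""
    K = plan.n_strata
    per_stratum = np.zeros((K, B))
    for k, idx in enumerate(plan.stratum_indices()):
        m = int(response[idx].sum())
        c, a, defined = _linear_form(config.statistic, x[idx], m)
        if not defined:
            continue
        if m == 0:
            per_stratum[k] = a
            continue
        n_k = len(idx)
        w = None
        if perm_weights is not None:
            w = perm_weights[idx]
            _check_weights(w, m, k)
        keys = _selection_keys(B, n_k, w, rng)
        if m < n_k:
            sel = np.argpartition(keys, m - 1, axis=1)[:, :m]
            contrib = c[sel].sum(axis=1)
        else:
            contrib = np.full(B, c.sum())
        per_stratum[k] = a + contrib

    if config.aggregation == "mean":
        return per_stratum.mean(axis=0)
    if config.aggregation == "weighted_mean":
        w = agg_weights
        return (per_stratum * w[:, None]).sum(axis=0) / w.sum()
    if config.aggregation == "mean_abs":
        return np.abs(per_stratum).mean(axis=0)
    if config.aggregation == "max_abs":
        return np.abs(per_stratum).max(axis=0)
    raise ParameterError(f"unknown aggregation {config.aggregation!r}")


def _p_value(null_abs_ge: int, B: int, rule: str) -> float:
    if rule == "raw_proportion":
        return null_abs_ge / B
    return (null_abs_ge + 1) / (B + 1)


def permutation_test(
    table: SiteTable,
    plan: StratificationPlan,
    config: PermutationConfig,
    permutation_weights: np.ndarray | None = None,
    aggregation_weights: np.ndarray | None = None,
) -> PermutationResult:
    """Run the stratified permutation test.

    ``permutation_weights`` defaults to the table's suitability scores when
    ``config.weighted_permutation`` is set; pass an explicit vector to weight
    by something else.  The two-sided p is the fraction of the B permuted
    aggregated statistics whose absolute value is at least the absolute
    observed statistic (ties count as extreme).

    Raises :class:`InfeasibleStrataError` (with the feasibility report
    attached) when the statistic is undefined in every stratum.
    """
    if len(plan.labels) != table.n_sites:
        raise ParameterError("plan does not cover the table")
    B = config.n_permutations

    x = table.stressor
    if config.log1p:
        x = log1_transform(x)
    response = table.response

    T_obs, stats = observed_statistic(table, plan, config, aggregation_weights)
    defined = np.array([s.defined for s in stats])
    if not defined.any():
        report = check_stratum_feasibility(table, plan)
        raise InfeasibleStrataError(
            "statistic undefined in every stratum; test refused", report=report
        )

    perm_w = None
    if config.weighted_permutation:
        perm_w = (
            np.asarray(permutation_weights, dtype=float)
            if permutation_weights is not None
            else table.suitability
        )

    rng = np.random.default_rng(config.seed)
    agg_w = _aggregation_weights(config, plan, aggregation_weights)
    draws = _null_draws(response, x, plan, config, B, rng, perm_w, agg_w)
    n_extreme = int((np.abs(draws) >= abs(T_obs) - _TIE_EPS).sum())
    p = _p_value(n_extreme, B, config.p_value_rule)

    report = check_stratum_feasibility(table, plan)
    logger.info(
        "permutation test: statistic=%s aggregation=%s weighted=%s K=%d B=%d "
        "seed=%d observed=%.6g p=%.6g (%d flagged strata)",
        config.statistic, config.aggregation, config.weighted_permutation,
        plan.n_strata, B, config.seed, T_obs, p, report.n_flagged,
    )
    return PermutationResult(
        observed=T_obs,
        per_stratum_observed=np.array([s.value for s in stats]),
        per_stratum_defined=defined,
        null_draws=draws,
        p_value=p,
        n_valid_strata=int(defined.sum()),
        stratum_sizes=plan.stratum_sizes(),
        config=config,
    )


# ---------------------------------------------------------------------------
# exhaustive-enumeration oracle
# ---------------------------------------------------------------------------

def _weighted_subset_prob(sel: tuple[int, ...], w: np.ndarray) -> float:
    """Probability that successive weighted sampling without replacement of
    len(sel) labels selects exactly the subset ``sel`` (any order)."""
    total = float(w.sum())
    memo: dict[frozenset, float] = {}

    def rec(remaining: frozenset, tot: float) -> float:
        if not remaining:
            return 1.0
        key = remaining
        if key in memo:
            return memo[key]
        p = 0.0
        for i in remaining:
            if w[i] > 0:
                p += (w[i] / tot) * rec(remaining - {i}, tot - w[i])
        memo[key] = p
        return p

    return rec(frozenset(sel), total)


def _enumerate_stratum(
    x: np.ndarray,
    m: int,
    statistic: str,
    w: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    """All subset values and probabilities for one stratum."""
    n = len(x)
    c, a, defined = _linear_form(statistic, x, m)
    if not defined:
        return np.array([0.0]), np.array([1.0])
    subsets = list(combinations(range(n), m))
    values = np.array([a + (c[list(s)].sum() if s else 0.0) for s in subsets])
    if w is None:
        probs = np.full(len(subsets), 1.0 / len(subsets))
    else:
        probs = np.array([_weighted_subset_prob(s, w) for s in subsets])
        total = probs.sum()
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise WeightingError(f"subset probabilities sum to {total}, not 1")
        probs = probs / total
    return values, probs


def exact_test_small(
    table: SiteTable,
    plan: StratificationPlan,
    config: PermutationConfig,
    permutation_weights: np.ndarray | None = None,
    aggregation_weights: np.ndarray | None = None,
    state_cap: int = EXACT_STATE_CAP,
) -> PermutationResult:
    """Exact stratified permutation test by full enumeration.

    Enumerates every within-stratum arrangement (Cartesian product across
    strata) with its exact probability — uniform, or the successive
    weighted-sampling probability in weighted mode — and returns the exact
    two-sided p.  Refuses when the state space exceeds ``state_cap``.
    """
    if len(plan.labels) != table.n_sites:
        raise ParameterError("plan does not cover the table")
    x = table.stressor
    if config.log1p:
        x = log1_transform(x)
    response = table.response

    T_obs, stats = observed_statistic(table, plan, config, aggregation_weights)
    defined = np.array([s.defined for s in stats])
    if not defined.any():
        report = check_stratum_feasibility(table, plan)
        raise InfeasibleStrataError(
            "statistic undefined in every stratum; test refused", report=report
        )

    perm_w = None
    if config.weighted_permutation:
        perm_w = (
            np.asarray(permutation_weights, dtype=float)
            if permutation_weights is not None
            else table.suitability
        )

    n_states = 1
    strata = plan.stratum_indices()
    for idx in strata:
        m = int(response[idx].sum())
        n_states *= math.comb(len(idx), m)
        if n_states > state_cap:
            raise StateSpaceError(
                f"state space exceeds {state_cap}; use permutation_test "
                "(Monte-Carlo) instead"
            )

    agg_w = _aggregation_weights(config, plan, aggregation_weights)
    K = plan.n_strata

    # combine strata one at a time; for mean-type aggregations track the
    # running (weighted) sum, for max_abs the running maximum of |v|
    agg = config.aggregation
    acc_vals = np.array([0.0])
    acc_probs = np.array([1.0])
    for k, idx in enumerate(strata):
        m = int(response[idx].sum())
        w_k = perm_w[idx] if perm_w is not None else None
        if w_k is not None:
            _check_weights(w_k, m, k)
        vals, probs = _enumerate_stratum(x[idx], m, config.statistic, w_k)
        if agg == "mean":
            t = vals
        elif agg == "weighted_mean":
            t = vals * agg_w[k]
        elif agg == "mean_abs":
            t = np.abs(vals)
        else:  # max_abs
            t = np.abs(vals)
        if agg == "max_abs":
            acc_vals = np.maximum.outer(acc_vals, t).ravel()
        else:
            acc_vals = np.add.outer(acc_vals, t).ravel()
        acc_probs = np.multiply.outer(acc_probs, probs).ravel()

    if agg in ("mean", "mean_abs"):
        acc_vals = acc_vals / K
    elif agg == "weighted_mean":
        acc_vals = acc_vals / agg_w.sum()

    p_exact = float(acc_probs[np.abs(acc_vals) >= abs(T_obs) - _TIE_EPS].sum())
    p_exact = min(p_exact, 1.0)

    logger.info(
        "exact test: %d states, observed=%.6g p=%.6g", len(acc_vals), T_obs, p_exact
    )
    return PermutationResult(
        observed=T_obs,
        per_stratum_observed=np.array([s.value for s in stats]),
        per_stratum_defined=defined,
        null_draws=acc_vals,
        p_value=p_exact,
        n_valid_strata=int(defined.sum()),
        stratum_sizes=plan.stratum_sizes(),
        config=config,
        exact=True,
        null_probabilities=acc_probs,
    )
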