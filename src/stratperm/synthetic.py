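"""Synthetic landscapes with known ground truth.

Emulates the statistical structure of a rare-species / rare-stressor survey:
~10% of sites occupied, ~10% exposed to the stressor, occupancy driven by
covariates through a logistic link, and a tunable true stressor effect
(zero for null calibration).  Stressor assignment can follow the same
covariate axis that drives occupancy (the confounding the stratified test
is built to absorb), and intensity-type stressors receive log-normal
magnitudes to mimic heavily skewed use data.

The suitability scores a real analysis would take from an external
occupancy model are produced here by :func:`fit_reference_suitability`, a
maximum-likelihood logistic regression on the covariates excluding the
stressor.  The permutation test consumes only the score, so any external
model of arbitrary complexity can be substituted through the suitability
column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import brentq
from scipy.special import expit

from .datatypes import PermutationConfig, SiteTable
from .errors import (
    CalibrationError,
    FitError,
    InfeasibleStrataError,
    ParameterError,
)
from .permute import permutation_test
from .stats import log1_transform
from .stratify import stratify_by_quantiles

logger = logging.getLogger("stratperm")


@dataclass
class SyntheticConfig:
    """Generative parameters of one synthetic landscape.

    ``stressor_effect`` is the true effect of the (transformed) stressor on
    the log-odds of occupancy; 0 gives an exact null.  The stressor follows
    the covariate-driven suitability axis with strength
    ``stressor_covariate_link`` (mild positive by default: the stressor
    tends to occur where the species could, which is the confounding the
    stratified test must absorb).  Intercepts are calibrated so the realised
    covariates hit the target prevalences.
    """

    n_sites: int = 2_000
    n_covariates: int = 3
    covariate_effects: tuple[float, ...] = (1.0, 0.6, 0.3)
    response_prevalence: float = 0.10
    stressor_prevalence: float = 0.10
    stressor_covariate_link: float = 0.5
    stressor_effect: float = 0.0
    stressor_type: str = "binary"
    intensity_log_mean: float = 3.0
    intensity_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 4:
            raise ParameterError("n_sites must be >= 4")
        if not (0 < self.response_prevalence < 1 and 0 < self.stressor_prevalence < 1):
            raise ParameterError("prevalences must be in (0, 1)")
        if len(self.covariate_effects) != self.n_covariates:
            raise ParameterError("covariate_effects length must equal n_covariates")
        if self.stressor_type not in ("binary", "intensity"):
            raise ParameterError("stressor_type must be 'binary' or 'intensity'")


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    """Solve mean(expit(b0 + eta)) = target for b0 on the realised sample."""

    def gap(b0):
        return float(expit(b0 + eta).mean() - target)

    lo, hi = -40.0, 40.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise CalibrationError(
            f"prevalence {target} unattainable: mean probability spans "
            f"[{expit(lo + eta).mean():.3g}, {expit(hi + eta).mean():.3g}]"
        )
    return brentq(gap, lo, hi, xtol=1e-12)


def generate_landscape(config: SyntheticConfig) -> tuple[SiteTable, dict]:
    """Draw one landscape; return the site table and the ground truth.

    Covariates are iid standard normal.  The stressor is assigned with
    probability expit(alpha0 + gamma * z) where z is the standardised
    covariate linear predictor; the response is Bernoulli with probability
    expit(beta0 + beta.x + beta_s * t(stressor)) where t is the identity for
    a binary stressor and log(1+x) for intensities.  The suitability column
    holds the true no-stressor occupancy probability (a perfect external
    model); refit it from data with :func:`fit_reference_suitability`.
    """
    rng = np.random.default_rng(config.seed)
    n, k = config.n_sites, config.n_covariates
    beta = np.asarray(config.covariate_effects, dtype=float)

    X = rng.standard_normal((n, k))
    eta_cov = X @ beta
    sd = eta_cov.std()
    z = (eta_cov - eta_cov.mean()) / sd if sd > 0 else np.zeros(n)

    alpha0 = _calibrate_intercept(config.stressor_covariate_link * z, config.stressor_prevalence)
    p_stressor = expit(alpha0 + config.stressor_covariate_link * z)
    present = rng.random(n) < p_stressor

    if config.stressor_type == "binary":
        stressor = present.astype(float)
        t = stressor
    else:
        stressor = present * rng.lognormal(config.intensity_log_mean, config.intensity_log_sd, size=n)
        t = log1_transform(stressor)

    beta0 = _calibrate_intercept(eta_cov + config.stressor_effect * t, config.response_prevalence)
    p_true = expit(beta0 + eta_cov + config.stressor_effect * t)
    response = (rng.random(n) < p_true).astype(np.int64)

    p_no_stressor = expit(beta0 + eta_cov)
    df = pd.DataFrame(
        {
            "site_id": [f"s{i:06d}" for i in range(n)],
            "response": response,
            "stressor": stressor,
            "suitability": p_no_stressor,
        }
    )
    for j in range(k):
        df[f"cov_{j}"] = X[:, j]

    truth = {
        "beta0": beta0,
        "alpha0": alpha0,
        "beta": beta,
        "beta_s": config.stressor_effect,
        "p_true": p_true,
        "p_no_stressor": p_no_stressor,
        "stressor_present": present,
    }
    return SiteTable(df), truth


@dataclass
class SuitabilityFit:
    params: np.ndarray
    bse: np.ndarray
    accuracy: float
    cutoff: float
    converged: bool


def covariate_columns(table: SiteTable) -> list[str]:
    return [c for c in table.data.columns if c.startswith("cov_")]


def fit_reference_suitability(
    table: SiteTable, covariates: np.ndarray | Sequence[str] | None = None
) -> tuple[SiteTable, SuitabilityFit]:
    """Fit a logistic suitability model on covariates excluding the stressor.

    Writes the fitted occupancy probabilities into the suitability column of
    a copy of the table and reports the classification accuracy at the
    cutoff maximising (true positives + true negatives) / n.
    """
    y = table.response
    if y.min() == y.max():
        raise FitError("response is constant; suitability model is degenerate")
    if covariates is None:
        cols = covariate_columns(table)
        if not cols:
            raise ParameterError("no cov_* columns and no covariates given")
        X = table.data[cols].to_numpy(dtype=float)
    elif isinstance(covariates, (list, tuple)) and covariates and isinstance(covariates[0], str):
        X = table.data[list(covariates)].to_numpy(dtype=float)
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]

    model = sm.Logit(y, sm.add_constant(X))
    try:
        fit = model.fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparationError etc.
        raise FitError(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", False) or np.isnan(fit.bse).any():
        raise FitError(
            "logistic fit did not converge; check for complete separation "
            "(rare-event data can be perfectly separable)"
        )
    probs = np.asarray(fit.predict())

    # accuracy at the optimal cutoff: scan the midpoints of sorted scores
    order = np.argsort(probs)
    sorted_y = y[order]
    n = len(y)
    n_pos = int(y.sum())
    # predicting positive above cutoff index i: correct = zeros below + ones above
    zeros_below = np.concatenate([[0], np.cumsum(1 - sorted_y)])
    ones_above = n_pos - np.concatenate([[0], np.cumsum(sorted_y)])
    correct = zeros_below + ones_above
    best = int(np.argmax(correct))
    accuracy = float(correct[best] / n)
    sorted_p = probs[order]
    if best == 0:
        cutoff = 0.0
    elif best == n:
        cutoff = 1.0
    else:
        cutoff = float((sorted_p[best - 1] + sorted_p[best]) / 2)

    out = table.copy()
    out.data["suitability"] = np.clip(probs, 0.0, 1.0)
    logger.info(
        "suitability fit: accuracy %.1f%% at cutoff %.3g, mean score %.4g",
        100 * accuracy, cutoff, probs.mean(),
    )
    return out, SuitabilityFit(
        params=np.asarray(fit.params),
        bse=np.asarray(fit.bse),
        accuracy=accuracy,
        cutoff=cutoff,
        converged=True,
    )


def run_pipeline(
    config: SyntheticConfig,
    perm_config: PermutationConfig,
    n_strata: int,
    refit_suitability: bool = True,
):
    """generate -> (re)fit suitability -> stratify -> permutation test."""
    table, truth = generate_landscape(config)
    if refit_suitability:
        table, _ = fit_reference_suitability(table)
    plan = stratify_by_quantiles(table, n_strata)
    result = permutation_test(table, plan, perm_config)
    return result, table, plan, truth


def calibration_suite(
    grid: Sequence[Mapping],
    replicates: int,
    perm_config: PermutationConfig,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical rejection rates of the full pipeline over a scenario grid.

    Each grid cell is a mapping of :class:`SyntheticConfig` field overrides,
    optionally with ``n_strata`` and ``weighted_permutation``/``statistic``
    overrides for the test.  For every cell, ``replicates`` landscapes are
    generated (seeds spawned deterministically from ``seed``), the pipeline
    is run, and the fraction of p <= alpha tabulated.  Replicates whose
    strata are all infeasible are counted separately, not silently dropped.
    """
    if replicates < 1:
        raise ParameterError("replicates must be >= 1")
    rows = []
    master = np.random.SeedSequence(seed)
    for cell_idx, cell in enumerate(grid):
        cell = dict(cell)
        n_strata = cell.pop("n_strata", perm_config.n_strata or 5)
        pc = perm_config
        for key in ("weighted_permutation", "statistic", "aggregation", "log1p"):
            if key in cell:
                pc = replace(pc, **{key: cell.pop(key)})
        children = master.spawn(replicates)
        pvals = []
        n_infeasible = 0
        n_failed = 0
        for child in children:
            rep_seed = int(child.generate_state(1)[0] % (2**31 - 1))
            cfg = SyntheticConfig(**cell, seed=rep_seed)
            pc_rep = replace(pc, seed=rep_seed)
            try:
                result, *_ = run_pipeline(cfg, pc_rep, n_strata)
                pvals.append(result.p_value)
            except InfeasibleStrataError:
                n_infeasible += 1
            except FitError:
                n_failed += 1
        pvals = np.asarray(pvals)
        rate = float((pvals <= alpha).mean()) if len(pvals) else float("nan")
        se = float(np.sqrt(rate * (1 - rate) / len(pvals))) if len(pvals) else float("nan")
        rows.append(
            {
                "cell": cell_idx,
                **{k: v for k, v in cell.items() if not isinstance(v, (list, tuple, np.ndarray))},
                "n_strata": n_strata,
                "replicates_ok": len(pvals),
                "n_infeasible": n_infeasible,
                "n_failed": n_failed,
                "rejection_rate": rate,
                "rejection_se": se,
                "mean_p": float(pvals.mean()) if len(pvals) else float("nan"),
            }
        )
        logger.info("calibration cell %d: %s", cell_idx, rows[-1])
    return pd.DataFrame(rows)
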