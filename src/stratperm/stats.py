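"""Stratum-level association statistics, stressor transforms, use-intensity
metrics, cross-strata aggregation, and stressor-covariate separation
diagnostics.

Two stratum statistics are offered.  For a binary stressor, the difference
in sample mean occupancy between stressor-positive and stressor-free sites;
negative values mean the stressor is associated with lower occupancy.  For a
continuous stressor, the point-biserial correlation, i.e. the Pearson
correlation between the 0/1 occupancy vector and the (optionally
log(1+x)-transformed) stressor intensity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .errors import (
    DiagnosticError,
    DomainError,
    NamedRequirementError,
    ParameterError,
)

STOCK_USE_WINDOW = 5  # years prior to and including the survey year


@dataclass
class StratumStatistic:
    """Association statistic within one stratum.

    ``defined`` is False when the statistic does not exist (an empty
    comparison group, or zero variance); the value is then reported as 0 so
    permutation loops never raise, and the flag lets callers count how often
    this happens.
    """

    stratum: int
    value: float
    n_sites: int
    defined: bool


def stat_mean_difference(
    response: np.ndarray, stressor_present: np.ndarray, stratum: int = 0
) -> StratumStatistic:
    """Difference in mean occupancy, stressor-present minus stressor-free."""
    response = np.asarray(response, dtype=float)
    present = np.asarray(stressor_present).astype(bool)
    if len(response) != len(present) or len(response) < 2:
        raise ParameterError("vectors must have equal length >= 2")
    n1 = int(present.sum())
    n0 = len(present) - n1
    if n1 == 0 or n0 == 0:
        return StratumStatistic(stratum, 0.0, len(response), False)
    value = float(response[present].mean() - response[~present].mean())
    return StratumStatistic(stratum, value, len(response), True)


def stat_point_biserial(
    response: np.ndarray, stressor_value: np.ndarray, stratum: int = 0
) -> StratumStatistic:
    """Point-biserial correlation: Pearson r of 0/1 response with intensity."""
    y = np.asarray(response, dtype=float)
    x = np.asarray(stressor_value, dtype=float)
    if len(y) != len(x) or len(y) < 2:
        raise ParameterError("vectors must have equal length >= 2")
    sy = y.std()
    sx = x.std()
    if sy == 0.0 or sx == 0.0:
        return StratumStatistic(stratum, 0.0, len(y), False)
    r = float(((y - y.mean()) * (x - x.mean())).mean() / (sy * sx))
    return StratumStatistic(stratum, r, len(y), True)


def log1_transform(stressor_value: np.ndarray) -> np.ndarray:
    """Elementwise natural log of (value + 1); maps 0 to 0, strictly increasing."""
    x = np.asarray(stressor_value, dtype=float)
    if np.any(x < 0):
        raise DomainError("log1_transform requires non-negative values")
    return np.log1p(x)


def stock_use_metrics(
    yearly_use: dict[int, float] | None,
    survey_year: int,
    area_ha: float | None = None,
    metrics: Sequence[str] = ("max_annual", "mean_annual_per_ha"),
) -> dict[str, float]:
    """Summarise reported use over the 5 years up to and including the survey.

    Years with no record count as zero.  ``max_annual`` is the maximum annual
    total over the window; ``mean_annual_per_ha`` is the 5-year mean of
    annual totals divided by the site area in hectares.
    """
    known = {"max_annual", "mean_annual_per_ha"}
    if not set(metrics) <= known:
        raise ParameterError(f"unknown metric in {metrics}")
    yearly_use = yearly_use or {}
    window = [yearly_use.get(y, 0.0) for y in range(survey_year - STOCK_USE_WINDOW + 1, survey_year + 1)]
    out: dict[str, float] = {}
    if "max_annual" in metrics:
        out["max_annual"] = float(max(window))
    if "mean_annual_per_ha" in metrics:
        if area_ha is None:
            raise NamedRequirementError("mean_annual_per_ha requires area_ha")
        if area_ha <= 0:
            raise ParameterError("area_ha must be positive")
        out["mean_annual_per_ha"] = float(np.mean(window) / area_ha)
    return out


def aggregate_strata(
    values: np.ndarray,
    defined_flags: np.ndarray | None = None,
    method: str = "mean",
    weights: np.ndarray | None = None,
) -> float:
    """Combine K stratum statistics into one overall test statistic.

    Undefined strata contribute 0 and stay in the denominator, so the number
    of strata (and hence the null distribution's support) never depends on
    the permuted labels.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ParameterError("cannot aggregate zero strata")
    if defined_flags is not None:
        values = np.where(np.asarray(defined_flags, dtype=bool), values, 0.0)
    if method == "mean":
        return float(values.mean())
    if method == "weighted_mean":
        if weights is None:
            raise ParameterError("weighted_mean needs weights")
        w = np.asarray(weights, dtype=float)
        if w.shape != values.shape or np.any(w < 0) or w.sum() == 0:
            raise ParameterError("weights must be non-negative, same length, not all zero")
        return float((values * w).sum() / w.sum())
    if method == "mean_abs":
        return float(np.abs(values).mean())
    if method == "max_abs":
        return float(np.abs(values).max())
    raise ParameterError(f"unknown aggregation {method!r}")


@dataclass
class SeparationReport:
    """Stressor-covariate separation diagnostics.

    A stressor well predicted by the occupancy-model covariates cannot carry
    much additional signal; ``per_covariate_r`` holds each covariate's
    Pearson correlation with the stressor and ``full_model_r2`` the R^2 of an
    OLS fit of the stressor on all covariates.
    """

    per_covariate_r: np.ndarray
    full_model_r2: float
    threshold: float
    warned: bool

    @property
    def max_abs_r(self) -> float:
        return float(np.nanmax(np.abs(self.per_covariate_r)))


def separation_diagnostics(
    covariates: np.ndarray,
    stressor_value: np.ndarray,
    threshold: float = 0.5,
) -> SeparationReport:
    """Check how separable the stressor is from the model covariates.

    Raises :class:`DiagnosticError` naming collinear columns when the
    covariate matrix is rank deficient; warns when any |r| >= ``threshold``.
    """
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    s = np.asarray(stressor_value, dtype=float)
    n, p = X.shape
    if len(s) != n:
        raise ParameterError("covariates and stressor length mismatch")
    if np.isnan(X).any() or np.isnan(s).any():
        raise ParameterError("missing values not allowed in diagnostics")
    if n < p + 2:
        raise ParameterError(f"need at least {p + 2} sites for {p} covariates")

    # incremental rank check to name the collinear columns
    bad: list[int] = []
    rank = 0
    kept = np.ones((n, 0))
    ones = np.ones((n, 1))
    for j in range(p):
        trial = np.hstack([ones, kept, X[:, [j]]])
        r = np.linalg.matrix_rank(trial)
        if r == rank + 2 or (rank == 0 and r == 2):
            kept = np.hstack([kept, X[:, [j]]])
            rank = kept.shape[1]
        else:
            bad.append(j)
    if bad:
        raise DiagnosticError(
            f"covariate columns {bad} are collinear with the others", columns=bad
        )

    rs = np.empty(p)
    s_sd = s.std()
    for j in range(p):
        xj = X[:, j]
        denom = xj.std() * s_sd
        rs[j] = np.nan if denom == 0 else ((xj - xj.mean()) * (s - s.mean())).mean() / denom

    fit = sm.OLS(s, sm.add_constant(X)).fit()
    r2 = float(fit.rsquared)

    warned = bool(np.nanmax(np.abs(rs)) >= threshold)
    if warned:
        warnings.warn(
            f"max |r| between stressor and a covariate is "
            f"{np.nanmax(np.abs(rs)):.3f} >= {threshold}; stratification may "
            "absorb the stressor signal",
            UserWarning,
            stacklevel=2,
        )
    return SeparationReport(rs, r2, threshold, warned)
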