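"""Core domain types.

A :class:`SiteTable` is the package's in-memory container: one row per site
(a lake or a meadow) carrying the binary occupancy response, the stressor
(binary presence or non-negative intensity such as stock nights), a
predicted suitability score in [0, 1] from an external occupancy model that
excludes the stressor, and optional area / complex-membership / per-year
use columns.  It wraps a pandas DataFrame so extra columns (covariates,
metadata) travel along untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError

REQUIRED_ROLES = ("site_id", "response", "stressor", "suitability")
OPTIONAL_ROLES = ("area_ha", "complex_id")

Statistic = Literal["mean_difference", "point_biserial"]
Aggregation = Literal["mean", "weighted_mean", "mean_abs", "max_abs"]
PValueRule = Literal["raw_proportion", "add_one"]


@dataclass
class SiteTable:
    """Validated per-site table.

    Parameters
    ----------
    data : pandas.DataFrame
        Must contain columns ``site_id``, ``response``, ``stressor``,
        ``suitability``; may contain ``area_ha``, ``complex_id`` and any
        number of extra columns.
    yearly_use : mapping site_id -> {year: stock nights}, optional
        Per-year stressor-use records, used by the 5-year use metrics.
    """

    data: pd.DataFrame
    yearly_use: dict[str, dict[int, float]] | None = None

    def __post_init__(self):
        self.data = self.data.reset_index(drop=True)

    # -- accessors -------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.data)

    @property
    def site_id(self) -> np.ndarray:
        return self.data["site_id"].to_numpy()

    @property
    def response(self) -> np.ndarray:
        return self.data["response"].to_numpy(dtype=np.int64)

    @property
    def stressor(self) -> np.ndarray:
        return self.data["stressor"].to_numpy(dtype=float)

    @property
    def suitability(self) -> np.ndarray:
        return self.data["suitability"].to_numpy(dtype=float)

    @property
    def area_ha(self) -> np.ndarray | None:
        if "area_ha" in self.data.columns:
            return self.data["area_ha"].to_numpy(dtype=float)
        return None

    @property
    def complex_id(self) -> np.ndarray | None:
        if "complex_id" in self.data.columns:
            return self.data["complex_id"].to_numpy()
        return None

    def validate(self) -> None:
        """Raise :class:`ValidationError` listing 1-based offending rows."""
        df = self.data
        problems: list[tuple[str, list[int]]] = []

        dup = df["site_id"].duplicated(keep=False)
        if dup.any():
            problems.append(("duplicate site_id", _rows(dup)))

        resp = df["response"]
        bad = ~resp.isin([0, 1])
        if bad.any():
            problems.append(("response not in {0, 1}", _rows(bad)))

        suit = pd.to_numeric(df["suitability"], errors="coerce")
        bad = suit.isna() | (suit < 0.0) | (suit > 1.0)
        if bad.any():
            problems.append(("suitability outside [0, 1]", _rows(bad)))

        stress = pd.to_numeric(df["stressor"], errors="coerce")
        bad = stress.isna() | (stress < 0.0)
        if bad.any():
            problems.append(("stressor negative or non-numeric", _rows(bad)))

        if "area_ha" in df.columns:
            area = pd.to_numeric(df["area_ha"], errors="coerce")
            bad = area.notna() & (area <= 0.0)
            if bad.any():
                problems.append(("area_ha not positive", _rows(bad)))

        if problems:
            msgs = "; ".join(
                f"{what} (rows {', '.join(map(str, rows))})" for what, rows in problems
            )
            allrows = sorted({r for _, rows in problems for r in rows})
            raise ValidationError(f"invalid site table: {msgs}", rows=allrows)

    def copy(self) -> "SiteTable":
        yu = None
        if self.yearly_use is not None:
            yu = {k: dict(v) for k, v in self.yearly_use.items()}
        return SiteTable(self.data.copy(), yu)


def _rows(mask: pd.Series) -> list[int]:
    # 1-based data rows, matching what a user sees below the header
    return [int(i) + 1 for i in np.flatnonzero(mask.to_numpy())]


@dataclass
class StratificationPlan:
    """Assignment of every site to one of K suitability strata.

    ``boundaries`` are the empirical quantiles at i/K (i = 1..K-1), kept for
    reporting; ``labels`` carry the actual per-site stratum index produced by
    the equal-size rank rule.
    """

    n_strata: int
    boundaries: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        # quantile construction requires K >= 2; a manually built single
        # stratum (no stratification) is a legitimate degenerate plan
        if self.n_strata < 1:
            raise ParameterError("n_strata must be >= 1")
        if len(self.boundaries) != self.n_strata - 1:
            raise ParameterError("need exactly K-1 boundaries")
        if np.any(np.diff(self.boundaries) < 0):
            raise ParameterError("boundaries must be non-decreasing")
        if self.labels.min() < 0 or self.labels.max() >= self.n_strata:
            raise ParameterError("labels out of range 0..K-1")

    def stratum_indices(self) -> list[np.ndarray]:
        return [np.flatnonzero(self.labels == k) for k in range(self.n_strata)]

    def stratum_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_strata)


@dataclass
class PermutationConfig:
    """Configuration of the stratified permutation test.

    Defaults follow the common workflow: B = 10,000 permutations, the
    difference-in-means statistic, unweighted within-stratum permutation and
    the unweighted mean across strata, with the two-sided p reported as the
    raw proportion of permuted statistics at least as extreme as observed.
    """

    statistic: Statistic = "mean_difference"
    n_permutations: int = 10_000
    aggregation: Aggregation = "mean"
    weighted_permutation: bool = False
    log1p: bool = False
    seed: int = 0
    p_value_rule: PValueRule = "raw_proportion"
    n_strata: int | None = None

    def __post_init__(self):
        if self.n_permutations < 1:
            raise ParameterError("n_permutations must be >= 1")
        if self.statistic not in ("mean_difference", "point_biserial"):
            raise ParameterError(f"unknown statistic {self.statistic!r}")
        if self.aggregation not in ("mean", "weighted_mean", "mean_abs", "max_abs"):
            raise ParameterError(f"unknown aggregation {self.aggregation!r}")
        if self.p_value_rule not in ("raw_proportion", "add_one"):
            raise ParameterError(f"unknown p_value_rule {self.p_value_rule!r}")
        if self.n_strata is not None and self.n_strata < 2:
            raise ParameterError("n_strata must be >= 2")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PermutationConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class PermutationResult:
    """Outcome of one stratified permutation test.

    ``observed`` is the aggregation of ``per_stratum_observed``; ``null_draws``
    holds the B aggregated statistics under within-stratum relabelling, and
    ``p_value`` the two-sided Monte-Carlo (or exact) p.  For exact-enumeration
    results ``null_probabilities`` carries the probability of each enumerated
    state and ``exact`` is True.
    """

    observed: float
    per_stratum_observed: np.ndarray
    per_stratum_defined: np.ndarray
    null_draws: np.ndarray
    p_value: float
    n_valid_strata: int
    stratum_sizes: np.ndarray
    config: PermutationConfig
    exact: bool = False
    null_probabilities: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.per_stratum_observed = np.asarray(self.per_stratum_observed, dtype=float)
        self.per_stratum_defined = np.asarray(self.per_stratum_defined, dtype=bool)
        self.null_draws = np.asarray(self.null_draws, dtype=float)
        if not (0.0 <= self.p_value <= 1.0):
            raise ParameterError("p_value outside [0, 1]")

    @property
    def n_draws(self) -> int:
        return len(self.null_draws)
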