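"""Quantile stratification on predicted suitability.

Sites are grouped into K strata of (near-)equal size by rank of their
suitability score, so that sites within a stratum are roughly equally
suitable for occupancy except for the stressor.  Equal-size strata maximise
the resolution of the within-stratum permutation null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import SiteTable, StratificationPlan
from .errors import DegenerateTiesError, ParameterError

logger = logging.getLogger("stratperm")


def stratify_by_quantiles(table: SiteTable, n_strata: int) -> StratificationPlan:
    """Assign each site to one of ``n_strata`` suitability strata.

    Ranks are computed with a stable sort, so ties are broken by site order
    and every stratum receives floor(n/K) or ceil(n/K) sites.  The reported
    boundaries are the empirical quantiles at i/K, i = 1..K-1.

    Raises
    ------
    ParameterError
        if K < 2 or there are fewer than 2K sites.
    DegenerateTiesError
        if more than half the sites share a single suitability value, in
        which case quantile strata carry no information.
    """
    if n_strata < 2:
        raise ParameterError("n_strata must be >= 2")
    n = table.n_sites
    if n < 2 * n_strata:
        raise ParameterError(f"need at least {2 * n_strata} sites for {n_strata} strata, got {n}")

    suit = table.suitability
    _, counts = np.unique(suit, return_counts=True)
    if counts.max() > n / 2:
        raise DegenerateTiesError(
            f"{counts.max()} of {n} sites share one suitability value; "
            f"{n_strata} quantile strata are degenerate"
        )

    order = np.argsort(suit, kind="stable")
    labels = np.empty(n, dtype=np.int64)
    labels[order] = (np.arange(n) * n_strata) // n
    boundaries = np.quantile(suit, np.arange(1, n_strata) / n_strata)
    plan = StratificationPlan(n_strata, boundaries, labels)
    logger.info(
        "stratified %d sites into K=%d strata, sizes %s",
        n, n_strata, plan.stratum_sizes().tolist(),
    )
    return plan


@dataclass
class StratumFeasibility:
    stratum: int
    n_sites: int
    n_occupied: int
    n_stressor_positive: int

    @property
    def flags(self) -> list[str]:
        out = []
        if self.n_occupied == 0:
            out.append("no occupied sites")
        elif self.n_occupied == self.n_sites:
            out.append("no unoccupied sites")
        if self.n_stressor_positive == 0:
            out.append("no stressor-positive sites")
        elif self.n_stressor_positive == self.n_sites:
            out.append("no stressor-free sites")
        return out

    @property
    def feasible(self) -> bool:
        return not self.flags


@dataclass
class FeasibilityReport:
    strata: list[StratumFeasibility]

    @property
    def n_flagged(self) -> int:
        return sum(not s.feasible for s in self.strata)

    @property
    def all_infeasible(self) -> bool:
        return all(not s.feasible for s in self.strata)

    def __str__(self) -> str:
        lines = []
        for s in self.strata:
            status = "; ".join(s.flags) if s.flags else "ok"
            lines.append(
                f"stratum {s.stratum}: n={s.n_sites} occupied={s.n_occupied} "
                f"stressor+={s.n_stressor_positive} [{status}]"
            )
        return "\n".join(lines)


def check_stratum_feasibility(table: SiteTable, plan: StratificationPlan) -> FeasibilityReport:
    """Report per-stratum occupancy and stressor counts.

    A stratum with no variation in either variable contributes an undefined
    (scored-as-zero) statistic; the report flags these so the user can judge
    whether K is too fine for the data.  Report-only: never raises.
    """
    resp = table.response
    pos = table.stressor > 0
    strata = []
    for k, idx in enumerate(plan.stratum_indices()):
        strata.append(
            StratumFeasibility(
                stratum=k,
                n_sites=len(idx),
                n_occupied=int(resp[idx].sum()),
                n_stressor_positive=int(pos[idx].sum()),
            )
        )
    report = FeasibilityReport(strata)
    for s in report.strata:
        logger.info(
            "stratum %d: n=%d occupied=%d stressor+=%d%s",
            s.stratum, s.n_sites, s.n_occupied, s.n_stressor_positive,
            "" if s.feasible else " FLAGGED: " + "; ".join(s.flags),
        )
    return report
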