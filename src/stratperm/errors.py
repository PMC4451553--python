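"""Exception hierarchy for stratperm.

All package errors derive from :class:`StratPermError` so callers can catch
everything this library raises with a single except clause.
"""

from __future__ import annotations


class StratPermError(Exception):
    """Base class for all stratperm errors."""


class SchemaError(StratPermError):
    """A required column is missing or the schema mapping is invalid."""


class ValidationError(StratPermError):
    """Input rows violate a table invariant.

    Attributes
    ----------
    rows : list[int]
        1-based data row numbers (excluding the header) of offending rows.
    """

    def __init__(self, message: str, rows: list[int] | None = None):
        super().__init__(message)
        self.rows = rows or []


class ParameterError(StratPermError, ValueError):
    """An argument is out of its documented range."""


class DomainError(StratPermError, ValueError):
    """A numeric input is outside the mathematical domain of an operation."""


class DegenerateTiesError(StratPermError):
    """More than half the sites share one suitability value; quantile strata
    are not meaningful."""


class NamedRequirementError(StratPermError):
    """An operation needs an optional column that the table does not carry."""


class WeightingError(StratPermError):
    """Weighted permutation cannot place an occupied label: a stratum has
    fewer positive-weight sites than occupied labels to assign."""


class AllocationError(StratPermError):
    """An allocation composition is malformed (parts off-grid or not
    summing to the complex total)."""


class InfeasibleStrataError(StratPermError):
    """Every stratum lacks within-stratum variation; the test statistic is
    undefined everywhere.  Carries the feasibility report."""

    def __init__(self, message: str, report=None):
        super().__init__(message)
        self.report = report


class StateSpaceError(StratPermError):
    """The exact-enumeration state space exceeds the cap; use the
    Monte-Carlo test instead."""


class CalibrationError(StratPermError):
    """Prevalence calibration of the synthetic generator failed."""


class DiagnosticError(StratPermError):
    """Separation diagnostics cannot be computed (e.g. collinear
    covariates).  Carries the offending column indices."""

    def __init__(self, message: str, columns: list[int] | None = None):
        super().__init__(message)
        self.columns = columns or []


class FitError(StratPermError):
    """The reference suitability model could not be fitted (degenerate
    response or complete separation)."""
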