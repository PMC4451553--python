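"""Reading and writing site tables, configs, plans and test results.

Site tables are comma-separated UTF-8 text with a header row.  A schema
mapping binds arbitrary column names to the roles the package needs
(``site_id``, ``response``, ``stressor``, ``suitability`` and the optional
``area_ha``, ``complex_id``), so field data never has to be renamed.
Per-year stressor-use records travel as ``use_<year>`` columns.

Results round-trip bit-exactly: the summary is JSON (Python's float repr is
shortest-round-trip) and the null draws a single column written at 17
significant digits.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    OPTIONAL_ROLES,
    REQUIRED_ROLES,
    PermutationConfig,
    PermutationResult,
    SiteTable,
    StratificationPlan,
)
from .errors import SchemaError

_USE_COL = re.compile(r"^use_(\d{4})$")


def read_site_table(path: str | Path, schema: Mapping[str, str] | None = None) -> SiteTable:
    """Read and validate a delimited site table.

    Parameters
    ----------
    path : path to a CSV file with a header row.
    schema : optional mapping role -> column name in the file.  Roles not in
        the mapping default to their own name.

    Raises
    ------
    SchemaError if a mapped/required column is absent;
    ValidationError (with row numbers) if any row violates an invariant.
    """
    path = Path(path)
    df = pd.read_csv(path)
    schema = dict(schema or {})

    rename: dict[str, str] = {}
    for role in REQUIRED_ROLES:
        col = schema.get(role, role)
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} (role {role!r}) not in {path.name}")
        if col != role:
            rename[col] = role
    for role in OPTIONAL_ROLES:
        col = schema.get(role, role)
        if col in df.columns and col != role:
            rename[col] = role
    df = df.rename(columns=rename)
    df["site_id"] = df["site_id"].astype(str)

    yearly_use = _extract_yearly_use(df)
    table = SiteTable(df, yearly_use)
    table.validate()
    return table


def _extract_yearly_use(df: pd.DataFrame) -> dict[str, dict[int, float]] | None:
    use_cols = {c: int(m.group(1)) for c in df.columns if (m := _USE_COL.match(c))}
    if not use_cols:
        return None
    out: dict[str, dict[int, float]] = {}
    for _, row in df.iterrows():
        rec = {
            year: float(row[col])
            for col, year in use_cols.items()
            if pd.notna(row[col]) and float(row[col]) != 0.0
        }
        out[str(row["site_id"])] = rec
    return out


def write_site_table(table: SiteTable, path: str | Path) -> None:
    df = table.data.copy()
    if table.yearly_use is not None:
        years = sorted({y for rec in table.yearly_use.values() for y in rec})
        for y in years:
            df[f"use_{y}"] = [
                table.yearly_use.get(str(sid), {}).get(y, 0.0) for sid in df["site_id"]
            ]
    df.to_csv(path, index=False)


# -- results -------------------------------------------------------------

def write_result(result: PermutationResult, path: str | Path) -> tuple[Path, Path]:
    """Write a result as ``<path>.json`` (summary) + ``<path>.null.txt``
    (one null draw per line).  Returns the two paths written."""
    path = Path(path)
    if path.suffix == ".json":
        path = path.with_suffix("")
    summary_path = path.with_suffix(".json")
    null_path = path.with_suffix(".null.txt")

    summary = {
        "observed": result.observed,
        "per_stratum_observed": [float(v) for v in result.per_stratum_observed],
        "per_stratum_defined": [bool(v) for v in result.per_stratum_defined],
        "p_value": result.p_value,
        "n_valid_strata": result.n_valid_strata,
        "stratum_sizes": [int(v) for v in result.stratum_sizes],
        "n_draws": result.n_draws,
        "exact": result.exact,
        "config": result.config.to_dict(),
    }
    summary_path.write_text(json.dumps(summary, indent=2) + "\n", encoding="utf-8")
    np.savetxt(null_path, result.null_draws, fmt="%.17g")
    return summary_path, null_path


def read_result(path: str | Path) -> PermutationResult:
    """Re-read a result written by :func:`write_result`, bit-exactly."""
    path = Path(path)
    if path.suffix == ".json":
        path = path.with_suffix("")
    summary = json.loads(path.with_suffix(".json").read_text(encoding="utf-8"))
    draws = np.loadtxt(path.with_suffix(".null.txt"), ndmin=1)
    return PermutationResult(
        observed=summary["observed"],
        per_stratum_observed=np.asarray(summary["per_stratum_observed"]),
        per_stratum_defined=np.asarray(summary["per_stratum_defined"], dtype=bool),
        null_draws=draws,
        p_value=summary["p_value"],
        n_valid_strata=summary["n_valid_strata"],
        stratum_sizes=np.asarray(summary["stratum_sizes"], dtype=np.int64),
        config=PermutationConfig.from_dict(summary["config"]),
        exact=summary["exact"],
    )


# -- plans and configs ---------------------------------------------------

def write_plan(plan: StratificationPlan, table: SiteTable, path: str | Path) -> None:
    pd.DataFrame({"site_id": table.site_id, "stratum": plan.labels}).to_csv(path, index=False)


def load_config(path: str | Path) -> PermutationConfig:
    """Load a flat key-value YAML config mirroring PermutationConfig."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise SchemaError(f"config {path} is not a flat mapping")
    return PermutationConfig.from_dict(data)


def builtin_config(name: str) -> PermutationConfig:
    """Load a shipped workflow template (``lake`` or ``meadow``)."""
    from importlib.resources import files

    res = files("stratperm").joinpath(f"configs/{name}.yaml")
    if not res.is_file():
        raise SchemaError(f"no builtin config named {name!r}")
    return PermutationConfig.from_dict(yaml.safe_load(res.read_text(encoding="utf-8")))
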