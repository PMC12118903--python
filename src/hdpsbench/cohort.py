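"""Cohort data model and delimited-text I/O.

A cohort is a subject-by-column table together with a role map declaring
which columns play which part in the analysis:

* ``exposure_col`` / ``outcome_col`` — binary 0/1 indicators;
* ``investigator_cols`` — binary or categorical covariates chosen from
  subject-matter knowledge, always adjusted for and never subject to
  empirical selection;
* ``lab_cols`` — continuous laboratory measurements;
* ``proxy_cols`` — binary 0/1 proxy ("recurrence") covariates, the pool
  that the selection methods operate on.

Cohorts are interchanged as RFC-4180 CSV with a header row; role maps as
YAML mapping role names to column-name lists.  Categorical investigator
covariates are expanded to reference-cell indicator columns on load
(sorted level order, lexicographically first level as reference) so that
downstream model matrices are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = ["ColumnRoles", "Cohort", "read_cohort", "write_cohort", "read_roles", "write_roles"]


class CohortError(ValueError):
    """Raised when a cohort table violates its declared roles."""


@dataclass(frozen=True)
class ColumnRoles:
    """Maps analysis roles to column names.  The five groups are disjoint."""

    exposure_col: str
    outcome_col: str
    investigator_cols: tuple[str, ...] = ()
    lab_cols: tuple[str, ...] = ()
    proxy_cols: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "investigator_cols", tuple(self.investigator_cols))
        object.__setattr__(self, "lab_cols", tuple(self.lab_cols))
        object.__setattr__(self, "proxy_cols", tuple(self.proxy_cols))
        groups = [
            (self.exposure_col,),
            (self.outcome_col,),
            self.investigator_cols,
            self.lab_cols,
            self.proxy_cols,
        ]
        flat = [c for g in groups for c in g]
        if len(set(flat)) != len(flat):
            dupes = sorted({c for c in flat if flat.count(c) > 1})
            raise CohortError(f"column roles overlap: {dupes}")

    @property
    def all_cols(self) -> list[str]:
        return (
            [self.exposure_col, self.outcome_col]
            + list(self.investigator_cols)
            + list(self.lab_cols)
            + list(self.proxy_cols)
        )


@dataclass
class Cohort:
    """A validated subject-level table plus its column roles."""

    table: pd.DataFrame
    roles: ColumnRoles
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._validate()

    @property
    def n(self) -> int:
        return len(self.table)

    def _validate(self) -> None:
        missing = [c for c in self.roles.all_cols if c not in self.table.columns]
        if missing:
            raise CohortError(f"cohort table is missing role columns: {missing}")
        if self.n < 1:
            raise CohortError("cohort has no rows")
        binary_cols = [self.roles.exposure_col, self.roles.outcome_col, *self.roles.proxy_cols]
        for col in binary_cols:
            vals = pd.unique(self.table[col])
            if not np.isin(vals, [0, 1]).all():
                bad = [v for v in vals if v not in (0, 1)][:5]
                raise CohortError(f"column {col!r} must be coded {{0,1}}; found values {bad}")

    # -- convenience accessors used throughout the pipeline ----------------

    @property
    def exposure(self) -> np.ndarray:
        return self.table[self.roles.exposure_col].to_numpy(dtype=float)

    @property
    def outcome(self) -> np.ndarray:
        return self.table[self.roles.outcome_col].to_numpy(dtype=float)

    def proxies(self) -> pd.DataFrame:
        return self.table[list(self.roles.proxy_cols)]

    def investigator(self) -> pd.DataFrame:
        return self.table[list(self.roles.investigator_cols)]

    def labs(self) -> pd.DataFrame:
        return self.table[list(self.roles.lab_cols)]

    def without_outcome(self) -> "Cohort":
        """Copy with the outcome column dropped (it will be regenerated)."""
        tab = self.table.drop(columns=[self.roles.outcome_col]).copy()
        tab[self.roles.outcome_col] = 0
        return Cohort(tab, self.roles)


def _expand_categoricals(table: pd.DataFrame, roles: ColumnRoles) -> tuple[pd.DataFrame, ColumnRoles]:
    """Expand non-{0,1} investigator columns into reference-cell indicators.

    Levels are sorted as strings; the first level is the reference and gets
    no column.  Indicator columns are named ``<col>_<level>``.
    """
    new_inv: list[str] = []
    out = table.copy()
    for col in roles.investigator_cols:
        vals = pd.unique(out[col].dropna())
        is_binary = len(vals) > 0 and all(v in (0, 1) for v in vals)
        if is_binary:
            new_inv.append(col)
            continue
        levels = sorted(str(v) for v in vals)
        as_str = out[col].astype(str)
        for level in levels[1:]:
            name = f"{col}_{level}"
            out[name] = (as_str == level).astype(int)
            new_inv.append(name)
        out = out.drop(columns=[col])
    return out, replace(roles, investigator_cols=tuple(new_inv))


def read_roles(path: str | Path) -> ColumnRoles:
    """Load a role map from a YAML file (role name -> column name or list)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return ColumnRoles(
        exposure_col=raw["exposure_col"],
        outcome_col=raw["outcome_col"],
        investigator_cols=tuple(raw.get("investigator_cols") or ()),
        lab_cols=tuple(raw.get("lab_cols") or ()),
        proxy_cols=tuple(raw.get("proxy_cols") or ()),
    )


def write_roles(roles: ColumnRoles, path: str | Path) -> None:
    payload = {
        "exposure_col": roles.exposure_col,
        "outcome_col": roles.outcome_col,
        "investigator_cols": list(roles.investigator_cols),
        "lab_cols": list(roles.lab_cols),
        "proxy_cols": list(roles.proxy_cols),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_cohort(path: str | Path, roles: ColumnRoles | str | Path) -> Cohort:
    """Read a CSV cohort table, validate it against ``roles`` and return it.

    Rows with any missing value in a role column are dropped (complete-case);
    the number dropped is logged and recorded on ``Cohort.warnings``.
    Categorical investigator covariates are expanded to indicator columns.
    """
    if not isinstance(roles, ColumnRoles):
        roles = read_roles(roles)
    table = pd.read_csv(path)
    missing = [c for c in roles.all_cols if c not in table.columns]
    if missing:
        raise CohortError(f"cohort file {path} is missing role columns: {missing}")
    table = table[roles.all_cols]
    n0 = len(table)
    table = table.dropna(axis=0, how="any").reset_index(drop=True)
    warnings: list[str] = []
    if len(table) < n0:
        msg = f"dropped {n0 - len(table)} rows with missing values (complete-case)"
        logger.warning(msg)
        warnings.append(msg)
    table, roles = _expand_categoricals(table, roles)
    return Cohort(table, roles, warnings=warnings)


def write_cohort(cohort: Cohort, path: str | Path, roles_path: str | Path | None = None) -> None:
    """Write the cohort table as CSV; optionally write its role map as YAML."""
    cohort.table.to_csv(path, index=False)
    if roles_path is not None:
        write_roles(cohort.roles, roles_path)
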