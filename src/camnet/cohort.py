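"""Cohort tables: patient-by-variable matrices of discrete state codes.

A :class:`CohortTable` couples an integer state matrix with a schema and a
per-cell missingness mask.  Files are plain CSV with a header of variable
names and ``NA`` for missing cells, so cohorts round-trip byte-stably.
Descriptive statistics (outcome-stratified contingency tables with Pearson
chi-square, no continuity correction) reproduce the printed cohort tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .schema import Schema, SchemaError

MISSING_TOKEN = "NA"


@dataclass
class ContingencySummary:
    """Outcome-by-state counts and the Pearson chi-square test for one variable."""

    variable: str
    table: np.ndarray  # shape (outcome levels, variable levels)
    chi2: float
    pvalue: float
    dof: int


class CohortTable:
    """Discrete cohort: rows are patients, columns are schema variables.

    Parameters
    ----------
    schema : Schema
    values : ndarray of int, shape (n, p)
        State indices; entries under the mask are ignored (kept as 0).
    missing : ndarray of bool, shape (n, p), optional
        True where a cell is unobserved.
    """

    def __init__(self, schema: Schema, values, missing=None):
        values = np.asarray(values, dtype=np.int64)
        if values.ndim != 2:
            raise SchemaError("cohort values must be 2-D")
        if values.shape[0] == 0:
            raise SchemaError("cohort must have at least one row")
        if values.shape[1] != len(schema):
            raise SchemaError(
                f"cohort has {values.shape[1]} columns, schema has "
                f"{len(schema)} variables"
            )
        if missing is None:
            missing = np.zeros(values.shape, dtype=bool)
        missing = np.asarray(missing, dtype=bool)
        if missing.shape != values.shape:
            raise SchemaError("missing mask shape mismatch")
        self.schema = schema
        self.values = values
        self.missing = missing
        self._validate()

    def _validate(self) -> None:
        bad: list[tuple[int, str, int]] = []
        for j, spec in enumerate(self.schema):
            col = self.values[:, j]
            obs = ~self.missing[:, j]
            off = np.nonzero(obs & ((col < 0) | (col >= spec.n_states)))[0]
            bad.extend((int(i), spec.name, int(col[i])) for i in off[:20])
        if bad:
            msg = "; ".join(f"row {i}, {n}={v}" for i, n, v in bad)
            raise SchemaError(f"state codes out of range: {msg}")

    # ------------------------------------------------------------ basic props
    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def columns(self) -> list[str]:
        return self.schema.names

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.columns.index(name)]

    def column_missing(self, name: str) -> np.ndarray:
        return self.missing[:, self.columns.index(name)]

    def is_fully_observed(self) -> bool:
        return not self.missing.any()

    def subset_rows(self, idx) -> "CohortTable":
        return CohortTable(self.schema, self.values[idx], self.missing[idx])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CohortTable)
            and self.columns == other.columns
            and np.array_equal(self.missing, other.missing)
            and np.array_equal(
                np.where(self.missing, 0, self.values),
                np.where(other.missing, 0, other.values),
            )
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.columns, dtype="Int64")
        return df.mask(self.missing)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, schema: Schema) -> "CohortTable":
        unknown = [c for c in df.columns if c not in schema]
        if unknown:
            raise SchemaError(f"unknown columns: {unknown}")
        if list(df.columns) != schema.names:
            missing_cols = [c for c in schema.names if c not in df.columns]
            if missing_cols:
                raise SchemaError(f"columns absent from table: {missing_cols}")
            df = df[schema.names]
        mask = df.isna().to_numpy()
        vals = df.fillna(0).to_numpy(dtype=np.int64)
        return cls(schema, vals, mask)


def read_cohort(path, schema: Schema) -> CohortTable:
    """Read a CSV cohort file (header = variable names, ``NA`` = missing)."""
    df = pd.read_csv(
        path, dtype="Int64", na_values=[MISSING_TOKEN], keep_default_na=False
    )
    return CohortTable.from_dataframe(df, schema)


def write_cohort(cohort: CohortTable, path) -> None:
    """Write a cohort as CSV; inverse of :func:`read_cohort`."""
    df = cohort.to_dataframe()
    df.to_csv(path, index=False, na_rep=MISSING_TOKEN)


def chi_square_by_outcome(cohort: CohortTable, variable: str) -> ContingencySummary:
    """Pearson chi-square of ``variable`` against the outcome.

    No continuity correction is applied, matching routine cohort descriptive
    statistics; dof = (levels-1)*(outcome levels-1).
    """
    outcome = cohort.schema.outcome.name
    if variable == outcome:
        raise ValueError("variable must differ from the outcome")
    j = cohort.columns.index(variable)
    k = cohort.columns.index(outcome)
    if cohort.missing[:, j].any() or cohort.missing[:, k].any():
        raise SchemaError("chi-square requires fully observed columns")
    spec = cohort.schema[variable]
    table = np.zeros((cohort.schema.outcome.n_states, spec.n_states))
    np.add.at(table, (cohort.values[:, k], cohort.values[:, j]), 1.0)
    return chi_square_from_counts(table, variable)


def chi_square_from_counts(table, variable: str = "") -> ContingencySummary:
    """Pearson chi-square (no Yates correction) from a count table."""
    table = np.asarray(table, dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate contingency table (all-zero row/column)")
    chi2, pvalue, dof, _ = stats.chi2_contingency(table, correction=False)
    return ContingencySummary(variable, table, float(chi2), float(pvalue), int(dof))
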