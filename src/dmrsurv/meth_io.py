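"""Parsing, validation, filtering and aggregation of quantitative methylation data.

Methylation matrices are pandas DataFrames with CpG-unit rows and patient
columns holding methylation fractions in [0, 1]; missing measurements are
NaN.  Survival tables are DataFrames indexed by patient id with columns
``time_months`` (> 0), ``event`` (0/1), ``age``, ``gender`` and ``uN``.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "load_matrix",
    "write_matrix",
    "validate_matrix",
    "load_survival",
    "write_survival",
    "filter_missing_samples",
    "average_by_region",
]

SURVIVAL_COLUMNS = ["time_months", "event", "age", "gender", "uN"]
_GENDERS = {"female", "male"}


class MatrixFormatError(ValueError):
    """Raised when a methylation matrix violates the format contract."""


def validate_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check a CpG × patient fraction matrix; returns it unchanged if valid."""
    if matrix.index.has_duplicates:
        dups = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise MatrixFormatError(f"duplicate CpG ids: {dups}")
    if matrix.columns.has_duplicates:
        dups = matrix.columns[matrix.columns.duplicated()].unique().tolist()
        raise MatrixFormatError(f"duplicate patient ids: {dups}")
    values = matrix.to_numpy(dtype=float)
    bad = (values < 0) | (values > 1)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise MatrixFormatError(
            f"methylation fraction out of [0, 1] at CpG {matrix.index[r]!r}, "
            f"patient {matrix.columns[c]!r}: {values[r, c]}"
        )
    return matrix


def load_matrix(path, *, transposed: bool = False, sep: str | None = None) -> pd.DataFrame:
    """Read a methylation matrix (CpG rows × patient columns) from TSV/CSV.

    Empty cells and ``NA``/``NaN`` are treated as missing.  ``transposed=True``
    accepts patient-row files and returns the canonical orientation.
    """
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA", "NaN", ""])
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise MatrixFormatError(f"non-numeric methylation value in {path}: {exc}") from exc
    if transposed:
        df = df.T
    return validate_matrix(df)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    matrix.to_csv(path, sep=sep, na_rep="NA", index_label="cpg_id")


def load_survival(path, *, sep: str = "\t") -> pd.DataFrame:
    """Read a survival table; index = patient id, validated columns."""
    df = pd.read_csv(path, sep=sep, dtype={"patient_id": str})
    missing = [c for c in ["patient_id", *SURVIVAL_COLUMNS] if c not in df.columns]
    if missing:
        raise MatrixFormatError(f"survival table missing columns: {missing}")
    df = df.set_index("patient_id")
    if df.index.has_duplicates:
        raise MatrixFormatError("duplicate patient ids in survival table")
    if (df["time_months"] <= 0).any():
        bad = df.index[df["time_months"] <= 0].tolist()
        raise MatrixFormatError(f"non-positive survival times for patients {bad}")
    if not df["event"].isin([0, 1]).all():
        raise MatrixFormatError("event indicator must be 0 or 1")
    unknown = set(df["gender"].dropna()) - _GENDERS
    if unknown:
        raise MatrixFormatError(f"unknown gender labels: {sorted(unknown)}")
    if not df["uN"].dropna().isin([0, 1]).all():
        raise MatrixFormatError("uN (ultrasound nodal status) must be 0 or 1")
    return df


def write_survival(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", na_rep="NA", index_label="patient_id")


def filter_missing_samples(matrix: pd.DataFrame, threshold: float = 0.6) -> pd.DataFrame:
    """Drop patients missing more than ``threshold`` of their CpG measurements.

    The inequality is strict: a patient missing exactly ``threshold`` of the
    CpG units is retained.  Dropped ids are logged.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    frac_missing = matrix.isna().mean(axis=0)
    dropped = frac_missing.index[frac_missing > threshold].tolist()
    if dropped:
        logger.info(
            "excluding %d sample(s) with > %.0f%% missing methylation: %s",
            len(dropped), 100 * threshold, dropped,
        )
    kept = matrix.drop(columns=dropped)
    if kept.shape[1] == 0:
        raise ValueError("all samples exceed the missingness threshold")
    return kept


def average_by_region(matrix: pd.DataFrame, region_map: Mapping[str, str]) -> pd.DataFrame:
    """Aggregate CpG rows to region rows by the mean of non-missing members.

    A region value is missing for a patient only when every member CpG is
    missing.  Regions keep the order of first appearance in ``region_map``.
    """
    if not region_map:
        raise ValueError("empty region map")
    unknown = [c for c in region_map if c not in matrix.index]
    if unknown:
        raise KeyError(f"region map references CpGs absent from the matrix: {unknown}")
    mapped = matrix.loc[list(region_map)]
    groups = pd.Series({c: region_map[c] for c in mapped.index}, name="region")
    out = mapped.groupby(groups, sort=False).mean()
    order = list(dict.fromkeys(region_map.values()))
    out = out.loc[order]
    out.index.name = "region_id"
    return out
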