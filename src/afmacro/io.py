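"""Tab-separated table formats for count, frequency and strain tables.

All artifacts are tidy (long) tables: one row per site x host observation.
A wide site x host export is provided as a convenience. Reading validates
the schema and the A <= D invariant; offending rows are rejected with their
row numbers, never silently fixed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TableFormatError",
    "COUNT_COLUMNS",
    "read_count_table",
    "read_frequency_table",
    "read_strain_table",
    "write_long_table",
    "to_wide",
]

COUNT_COLUMNS = ["site_id", "gene_id", "site_class", "host_id", "A", "D"]
SITE_CLASSES = {"synonymous", "nonsynonymous"}


class TableFormatError(ValueError):
    """A table violates the expected schema or an invariant."""


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s) {missing}")


def _to_int(df: pd.DataFrame, column: str, path) -> pd.Series:
    coerced = pd.to_numeric(df[column], errors="coerce")
    bad = coerced.isna() | (coerced != np.floor(coerced.fillna(0)))
    if bad.any():
        row = int(bad.idxmax()) + 2  # 1-based, plus header line
        raise TableFormatError(
            f"{path}: non-integer value {df.loc[bad.idxmax(), column]!r} in column "
            f"{column!r} at line {row}"
        )
    return coerced.astype(np.int64)


def read_count_table(path) -> pd.DataFrame:
    """Read and validate a long count table (site x host read counts).

    Requires the six columns site_id, gene_id, site_class, host_id, A, D;
    rejects rows with A > D or duplicated (site_id, host_id) pairs.
    An empty file with a valid header yields an empty table.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in COUNT_COLUMNS[:4]})
    _require_columns(df, COUNT_COLUMNS, path)
    df = df[COUNT_COLUMNS]
    if df.empty:
        return df.astype({"A": np.int64, "D": np.int64})
    df["A"] = _to_int(df, "A", path)
    df["D"] = _to_int(df, "D", path)
    neg = (df["A"] < 0) | (df["D"] < 0)
    if neg.any():
        raise TableFormatError(
            f"{path}: negative read count at line {int(neg.idxmax()) + 2}"
        )
    bad = df["A"] > df["D"]
    if bad.any():
        rows = [int(i) + 2 for i in df.index[bad][:5]]
        raise TableFormatError(
            f"{path}: A > D at line(s) {rows} — alternate reads cannot exceed depth"
        )
    unknown = ~df["site_class"].isin(SITE_CLASSES)
    if unknown.any():
        raise TableFormatError(
            f"{path}: site_class must be one of {sorted(SITE_CLASSES)}, "
            f"got {df.loc[unknown.idxmax(), 'site_class']!r}"
        )
    dup = df.duplicated(subset=["site_id", "host_id"])
    if dup.any():
        raise TableFormatError(
            f"{path}: duplicated (site_id, host_id) pair at line {int(dup.idxmax()) + 2}"
        )
    return df


def read_frequency_table(path) -> pd.DataFrame:
    """Read a long frequency table (site_id, host_id, f, D [, depth_ok])."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"site_id": str, "host_id": str})
    _require_columns(df, ["site_id", "host_id", "f", "D"], path)
    if ((df["f"] < 0) | (df["f"] > 1)).any():
        raise TableFormatError(f"{path}: frequencies must lie in [0, 1]")
    if "depth_ok" in df.columns:
        df["depth_ok"] = df["depth_ok"].astype(bool)
    return df


def read_strain_table(path) -> pd.DataFrame:
    """Read strain-structure indicators (species_id, host_id, has_strains)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"species_id": str, "host_id": str})
    _require_columns(df, ["species_id", "host_id", "has_strains"], path)
    if not df["has_strains"].isin([0, 1]).all():
        raise TableFormatError(f"{path}: has_strains must be 0 or 1")
    return df


def write_long_table(records: pd.DataFrame, path) -> None:
    """Write any tabular result as tab-separated text with a header.

    Round-trips count tables bit-exactly through read_count_table.
    """
    if records is None:
        raise ValueError("records must not be None")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    records.to_csv(path, sep="\t", index=False)


def to_wide(freqs: pd.DataFrame, values: str = "f") -> pd.DataFrame:
    """Pivot a long frequency table to a site x host matrix."""
    return freqs.pivot(index="site_id", columns="host_id", values=values)
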