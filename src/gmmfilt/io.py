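"""Readers and writers for expression matrices and label files.

Supported matrix dialects:

* plain TSV/CSV — first column gene ids, header row sample ids, numeric body;
* GCT — two header lines (``#1.2`` then dimensions), ``Name``/``Description``
  columns; the ``Description`` column is ignored.

Labels are a two-column TSV (sample_id, group) with exactly two distinct
group values.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .signals import ExpressionMatrix, Scale


def read_expression(path, scale: Scale = "log2", sep: str | None = None) -> ExpressionMatrix:
    """Read a TSV/CSV or GCT expression matrix."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#1.2"):
        return _read_gct(path, scale)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values in expression matrix")
    return ExpressionMatrix(
        values=df.to_numpy(dtype=float),
        gene_ids=df.index.to_numpy(dtype=str),
        sample_ids=df.columns.to_numpy(dtype=str),
        scale=scale,
    )


def _read_gct(path: Path, scale: Scale) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", skiprows=2)
    if df.columns[0] != "Name" or df.columns[1] != "Description":
        raise ValueError(f"{path}: not a GCT file (expected Name/Description columns)")
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values in expression matrix")
    return ExpressionMatrix(
        values=df.iloc[:, 2:].to_numpy(dtype=float),
        gene_ids=df["Name"].to_numpy(dtype=str),
        sample_ids=df.columns[2:].to_numpy(dtype=str),
        scale=scale,
    )


def write_expression(m: ExpressionMatrix, path, sep: str = "\t") -> None:
    pd.DataFrame(m.values, index=pd.Index(m.gene_ids, name="gene_id"),
                 columns=m.sample_ids).to_csv(path, sep=sep)


def read_labels(path) -> pd.Series:
    """Two-column TSV (sample_id, group); exactly two distinct groups."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: labels file needs two columns (sample_id, group)")
    if df.iloc[0, 0] in ("sample_id", "sample"):  # tolerate a header line
        df = df.iloc[1:]
    s = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].to_numpy())
    if s.index.has_duplicates:
        raise ValueError(f"{path}: duplicated sample ids in labels")
    if s.nunique() != 2:
        raise ValueError(f"{path}: expected exactly two groups, got {sorted(s.unique())}")
    return s


def write_labels(labels: dict | pd.Series, path) -> None:
    pd.Series(labels).rename_axis("sample_id").to_frame("group").to_csv(
        path, sep="\t", header=False
    )
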