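"""TSV readers and writers for the cohort tables.

All files are UTF-8 tab-separated with a header row, an ``id`` first
column, and ``NA`` for missing values.  Floats are written with a fixed
repr-stable format so that identical analyses produce byte-identical
files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_table",
    "read_table",
    "write_kinship",
    "read_kinship",
    "write_kinship_long",
]

_FLOAT_FMT = "%.10g"


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write an id-indexed table as TSV (index label ``id``)."""
    df.to_csv(path, sep="\t", na_rep="NA", index_label="id", float_format=_FLOAT_FMT)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id", na_values=["NA"])


def write_kinship(K: pd.DataFrame, path: str | Path) -> None:
    """Square kinship TSV with matching id header and index."""
    K.to_csv(path, sep="\t", index_label="id", float_format=_FLOAT_FMT)


def read_kinship(path: str | Path) -> pd.DataFrame:
    K = pd.read_csv(path, sep="\t", index_col="id")
    K.columns.name = None
    if list(K.index) != list(K.columns):
        raise ValueError("kinship file ids differ between rows and columns")
    return K


def write_kinship_long(K: pd.DataFrame, path: str | Path, tol: float = 0.0) -> None:
    """Sparse long-format (id1, id2, value) upper triangle incl. diagonal."""
    vals = K.to_numpy()
    ids = list(K.index)
    rows = []
    for i in range(len(ids)):
        for j in range(i, len(ids)):
            if abs(vals[i, j]) > tol:
                rows.append((ids[i], ids[j], vals[i, j]))
    out = pd.DataFrame(rows, columns=["id1", "id2", "value"])
    out.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
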