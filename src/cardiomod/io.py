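"""Reading and writing of expression matrices and cell metadata.

The primary on-disk format is plain TSV: the expression matrix has gene
identifiers in the first column and a header row of cell identifiers;
metadata is a TSV with at least ``cell_id`` and ``stage`` columns and
optional ``genotype`` and ``area_um2`` columns. Matrix Market (``.mtx``)
input with sidecar row/column name files is supported as an alternative.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


METADATA_REQUIRED = ("cell_id", "stage")
METADATA_OPTIONAL = ("genotype", "area_um2")


def read_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Read a genes x cells expression matrix from TSV or MTX.

    For ``.mtx`` input, ``<path>.rownames`` and ``<path>.colnames`` (one
    identifier per line) must sit next to the matrix file.
    """
    path = os.fspath(path)
    if path.endswith(".mtx"):
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = _read_names(path + ".rownames")
        cells = _read_names(path + ".colnames")
        return pd.DataFrame(np.asarray(mat, dtype=float), index=genes, columns=cells)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df.astype(float)


def write_matrix(matrix: pd.DataFrame, path: str | os.PathLike) -> None:
    path = os.fspath(path)
    if path.endswith(".mtx"):
        scipy.io.mmwrite(path, scipy.sparse.csr_matrix(matrix.to_numpy()))
        _write_names(matrix.index, path + ".rownames")
        _write_names(matrix.columns, path + ".colnames")
    else:
        matrix.to_csv(path, sep="\t", index_label="gene_id")


def read_metadata(path: str | os.PathLike) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"cell_id": str})
    missing = [c for c in METADATA_REQUIRED if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata is missing required column(s): {missing}")
    return meta.set_index("cell_id", drop=False)


def write_metadata(meta: pd.DataFrame, path: str | os.PathLike) -> None:
    meta.to_csv(path, sep="\t", index=False)


def _read_names(path: str) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def _write_names(names, path: str) -> None:
    with open(path, "w") as fh:
        for name in names:
            fh.write(f"{name}\n")


def log2_rpkm(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2(RPKM + 1) transform used throughout the network analysis."""
    if (matrix.to_numpy() < 0).any():
        raise ValueError("expression matrix contains negative values")
    return np.log2(matrix + 1.0)
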