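"""Cell and gene quality-control filters and cell-to-cell heterogeneity.

Cells are kept when strictly more than ``min_genes`` genes are detected
above an RPKM threshold (detection is a strict ``>`` comparison); genes
are kept when expressed at RPKM >= threshold (inclusive) in at least a
given number or fraction of cells. Transcriptional heterogeneity is the
distribution of pairwise Pearson correlations between cells of the same
group, computed by default on log2(RPKM+1) over a heterogeneity gene set
(RPKM >= 10 in >= 20% of cells).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import log2_rpkm

__all__ = [
    "QCReport",
    "count_detected_genes",
    "filter_cells",
    "filter_genes",
    "pairwise_cell_correlation",
]


@dataclass
class QCReport:
    """Per-cell detection counts and the resulting pass/fail decisions."""

    detected_genes: pd.Series
    passed: pd.Series
    rpkm_threshold: float
    min_genes: int
    n_excluded_pairs: int = 0
    correlations: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def pass_fraction(self) -> float:
        return float(self.passed.mean())

    def summary(self) -> dict:
        return {
            "n_cells": int(len(self.passed)),
            "n_pass": int(self.passed.sum()),
            "pass_fraction": self.pass_fraction,
            "rpkm_threshold": self.rpkm_threshold,
            "min_genes": self.min_genes,
        }


def count_detected_genes(
    matrix: pd.DataFrame, rpkm_threshold: float = 0.1
) -> pd.Series:
    """Number of genes per cell with expression strictly above the threshold."""
    if matrix.size == 0:
        raise ValueError("empty expression matrix")
    if rpkm_threshold < 0:
        raise ValueError("rpkm_threshold must be non-negative")
    return (matrix > rpkm_threshold).sum(axis=0).rename("detected_genes")


def filter_cells(
    matrix: pd.DataFrame,
    meta: pd.DataFrame | None = None,
    min_genes: int = 5000,
    rpkm_threshold: float = 0.1,
) -> tuple[pd.DataFrame, QCReport]:
    """Retain cells detecting strictly more than ``min_genes`` genes.

    Returns the filtered matrix (and a report with per-cell counts and
    the pass fraction). Metadata, when given, is used only to check that
    every cell is annotated.
    """
    counts = count_detected_genes(matrix, rpkm_threshold)
    if meta is not None:
        missing = matrix.columns.difference(meta["cell_id"])
        if len(missing):
            raise ValueError(f"cells missing from metadata: {list(missing)[:5]}")
    passed = counts > min_genes
    report = QCReport(counts, passed, rpkm_threshold, min_genes)
    if not passed.any():
        raise ValueError(
            f"no cell detects more than {min_genes} genes at "
            f"RPKM > {rpkm_threshold}"
        )
    return matrix.loc[:, passed[passed].index], report


def filter_genes(
    matrix: pd.DataFrame,
    rpkm_threshold: float = 10.0,
    min_cells: int | None = None,
    min_fraction: float | None = None,
) -> pd.Index:
    """Genes expressed at >= ``rpkm_threshold`` (inclusive) in enough cells.

    Exactly one of ``min_cells`` / ``min_fraction`` must be given; a
    fraction is converted to ``ceil(min_fraction * n_cells)`` cells.
    """
    if (min_cells is None) == (min_fraction is None):
        raise ValueError("give exactly one of min_cells or min_fraction")
    if min_fraction is not None:
        if not 0.0 < min_fraction <= 1.0:
            raise ValueError("min_fraction must lie in (0, 1]")
        min_cells = math.ceil(min_fraction * matrix.shape[1])
    n_above = (matrix >= rpkm_threshold).sum(axis=1)
    return matrix.index[n_above >= min_cells]


def pairwise_cell_correlation(
    matrix: pd.DataFrame,
    group_labels: pd.Series,
    gene_filter: pd.Index | None = None,
    log_transform: bool = True,
) -> tuple[dict[str, np.ndarray], int]:
    """Within-group pairwise Pearson correlations between cells.

    For each group label, returns the correlations of all unordered
    cell pairs over ``gene_filter`` genes (default: RPKM >= 10 in >= 20%
    of cells), computed on log2(RPKM+1) unless ``log_transform=False``.
    Pairs involving a zero-variance cell are undefined and excluded; the
    second return value counts them. Groups with < 2 cells are skipped
    with a warning.
    """
    if gene_filter is None:
        gene_filter = filter_genes(matrix, 10.0, min_fraction=0.2)
    sub = matrix.loc[gene_filter]
    if log_transform:
        sub = log2_rpkm(sub)
    group_labels = group_labels.reindex(sub.columns)
    out: dict[str, np.ndarray] = {}
    n_excluded = 0
    for group in pd.unique(group_labels.dropna()):
        cells = group_labels.index[group_labels == group]
        if len(cells) < 2:
            warnings.warn(f"group {group!r} has < 2 cells; skipped")
            continue
        x = sub[cells].to_numpy()
        sd = x.std(axis=0)
        ok = sd > 0
        n_ok = int(ok.sum())
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(x[:, ok], rowvar=False)
        vals = corr[np.triu_indices(n_ok, k=1)]
        n_excluded += len(cells) * (len(cells) - 1) // 2 - len(vals)
        out[group] = vals
    return out, n_excluded
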