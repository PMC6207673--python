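"""Integration of single-cell morphology (area) with the transcriptome.

Cells measured for area (um^2) before lysis are placed by principal
component analysis of their expression profiles; the PCs, the module
eigengenes and individual genes are then correlated (Pearson) with cell
area to rank the transcriptional programs that track morphological
hypertrophy, and the top-N area-correlated genes are extracted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import log2_rpkm

__all__ = [
    "pca_cells",
    "correlate_with_area",
    "top_correlated_genes",
    "morphology_report",
]


def pca_cells(
    matrix: pd.DataFrame,
    n_components: int | None = None,
    log_transform: bool = True,
) -> tuple[pd.DataFrame, pd.Series]:
    """PCA of cells on per-gene standardized expression.

    ``matrix`` is genes x cells (RPKM scale unless ``log_transform`` is
    False). Returns (cells x components scores, variance-explained per
    component). Sign convention: the largest-magnitude gene loading of
    each component is positive.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 cells for PCA")
    x = (log2_rpkm(matrix) if log_transform else matrix).to_numpy(dtype=float)
    sd = x.std(axis=1)
    x = x[sd > 0]
    if x.shape[0] < 2:
        raise ValueError("fewer than 2 genes with variance")
    z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    k = min(n_components or len(s), len(s))
    scores = (vt[:k].T * s[:k])  # cells x components
    for j in range(k):
        lead = np.argmax(np.abs(u[:, j]))
        if u[lead, j] < 0:
            u[:, j] *= -1
            scores[:, j] *= -1
    var_exp = s[:k] ** 2 / (s**2).sum()
    cols = [f"PC{i + 1}" for i in range(k)]
    return (
        pd.DataFrame(scores, index=matrix.columns, columns=cols),
        pd.Series(var_exp, index=cols, name="variance_explained"),
    )


def correlate_with_area(
    profiles: pd.DataFrame, area: pd.Series
) -> pd.DataFrame:
    """Pearson correlation of each profile with cell area, ranked.

    ``profiles`` is cells x features (PC scores, eigengene values over
    cells, or gene profiles transposed); ``area`` must cover all cells.
    Zero-variance profiles are reported with NaN r and excluded from the
    ranking order. Constant area raises.
    """
    area = area.reindex(profiles.index)
    if area.isna().any():
        missing = list(profiles.index[area.isna()])[:5]
        raise ValueError(f"area missing for cells: {missing}")
    if len(area) < 3:
        raise ValueError("need at least 3 cells")
    a = area.to_numpy(dtype=float)
    if a.std() == 0:
        raise ValueError("cell area is constant; correlations undefined")
    x = profiles.to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    ac = a - a.mean()
    denom = np.sqrt((xc**2).sum(axis=0)) * np.sqrt((ac**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ ac) / denom
    r[denom == 0] = np.nan
    out = pd.DataFrame({"r": r}, index=profiles.columns)
    out["rank"] = out["r"].rank(ascending=False)
    return out.sort_values("r", ascending=False, na_position="last")


def top_correlated_genes(
    matrix: pd.DataFrame,
    area: pd.Series,
    n: int = 300,
    log_transform: bool = True,
    min_cells_detected: int = 1,
    detection_threshold: float = 0.1,
) -> pd.DataFrame:
    """Top-``n`` genes by Pearson correlation with cell area.

    Genes must be detected (> ``detection_threshold``) in at least
    ``min_cells_detected`` cells to enter the ranking; ties are broken
    lexicographically by gene id.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    detected = (matrix > detection_threshold).sum(axis=1) >= min_cells_detected
    sub = matrix.loc[detected]
    x = (log2_rpkm(sub) if log_transform else sub).T  # cells x genes
    corr = correlate_with_area(x, area)
    corr = corr.loc[
        sorted(corr.index, key=lambda g: (-corr.loc[g, "r"] if np.isfinite(corr.loc[g, "r"]) else np.inf, g))
    ]
    return corr.head(min(n, len(corr)))


def morphology_report(
    matrix: pd.DataFrame,
    area: pd.Series,
    eigengenes: pd.DataFrame | None = None,
    n_components: int = 10,
    top_n: int = 300,
) -> dict:
    """PC-area, module-area and gene-area correlations in one pass.

    Returns a dict with PC scores and variance explained, each
    correlation table, and the top-``top_n`` area-correlated genes.
    """
    scores, var_exp = pca_cells(matrix, n_components=n_components)
    report = {
        "pc_scores": scores,
        "variance_explained": var_exp,
        "pc_area_correlation": correlate_with_area(scores, area),
        "gene_area_correlation": top_correlated_genes(matrix, area, n=top_n),
    }
    if eigengenes is not None:
        report["module_area_correlation"] = correlate_with_area(eigengenes.T, area)
    return report
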