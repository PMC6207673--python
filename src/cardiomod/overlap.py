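"""Module overlap testing and stage-specific module discovery.

Two module sets defined on a shared gene universe are compared with
one-sided Fisher exact tests (hypergeometric upper tail) on each module
pair's 2x2 membership table. Stage-specific modules are found by
building the co-expression network twice -- on all cells and on all
cells minus one stage -- and flagging the full-network modules whose
best overlap with any reduced-network module falls below a significance
threshold: a module whose co-expression exists only while that stage's
cells are present has no counterpart in the reduced network. The same
machinery compares module sets across datasets (e.g., across species
through an ortholog map).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .network import UNASSIGNED, CoexpressionNetwork, NetworkParams

__all__ = [
    "OverlapResult",
    "module_overlap",
    "detect_stage_specific",
    "cross_dataset_overlap",
]


@dataclass
class OverlapResult:
    """Pairwise module overlap table and per-module best matches.

    ``table`` has one row per (module_a, module_b) pair with the overlap
    count, module sizes, universe size, the one-sided Fisher p
    (hypergeometric upper tail), its -log10, and a Bonferroni-adjusted
    p over all pairs. ``best_match`` gives, per A-module, the maximal
    -log10 p over B-modules; ``specific`` flags A-modules whose best
    match stays below ``threshold_neglogp``.
    """

    table: pd.DataFrame
    best_match: pd.Series
    specific: pd.Series
    threshold_neglogp: float
    universe_size: int


def _module_map(labels: pd.Series, universe: pd.Index) -> dict[str, set]:
    labels = labels.reindex(universe)
    out = {}
    for mod in pd.unique(labels.dropna()):
        if mod == UNASSIGNED or mod == -1:
            continue
        out[mod] = set(labels.index[labels == mod])
    return out


def module_overlap(
    labels_a: pd.Series,
    labels_b: pd.Series,
    universe: pd.Index | list,
    threshold_neglogp: float = 10.0,
) -> OverlapResult:
    """One-sided Fisher overlap test for every module pair.

    ``labels_a``/``labels_b`` map genes to module ids ("unassigned"
    excluded from the module sets but retained in the universe). For a
    pair with overlap x, sizes nA and nB in a universe of N genes,
    p = P(X >= x), X ~ Hypergeometric(N, nA, nB).
    """
    universe = pd.Index(universe)
    if len(universe) == 0:
        raise ValueError("empty gene universe")
    mods_a = _module_map(labels_a, universe)
    mods_b = _module_map(labels_b, universe)
    n_univ = len(universe)
    rows = []
    for ma in sorted(mods_a, key=str):
        for mb in sorted(mods_b, key=str):
            inter = len(mods_a[ma] & mods_b[mb])
            p = float(hypergeom.sf(inter - 1, n_univ, len(mods_a[ma]), len(mods_b[mb])))
            p = min(max(p, 5e-324), 1.0)
            rows.append(
                {
                    "module_a": ma,
                    "module_b": mb,
                    "overlap": inter,
                    "size_a": len(mods_a[ma]),
                    "size_b": len(mods_b[mb]),
                    "universe": n_univ,
                    "p": p,
                    "neg_log10_p": -np.log10(p),
                }
            )
    table = pd.DataFrame(rows)
    if not table.empty:
        n_pairs = len(table)
        table["p_bonferroni"] = np.minimum(table["p"] * n_pairs, 1.0)
        best = table.groupby("module_a")["neg_log10_p"].max()
    else:
        table["p_bonferroni"] = []
        best = pd.Series(dtype=float)
    specific = best < threshold_neglogp
    return OverlapResult(table, best, specific, threshold_neglogp, n_univ)


def detect_stage_specific(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    excluded_stage: str,
    params: NetworkParams | None = None,
    threshold_neglogp: float = 10.0,
    min_cells: int = 30,
) -> tuple[list, OverlapResult, object, object]:
    """Find modules whose co-expression requires one stage's cells.

    Fits the network on all cells (set A) and on all cells except
    ``excluded_stage`` (set B) with identical parameters, then runs the
    Fisher overlap match on the shared gene universe. A-modules whose
    best-match -log10 p falls below the threshold are stage-specific.
    Returns (flagged modules, overlap result, full fit, reduced fit).
    """
    stages = meta["stage"]
    if excluded_stage not in set(stages):
        raise ValueError(f"stage {excluded_stage!r} absent from metadata")
    keep = meta.index[stages != excluded_stage]
    keep = [c for c in matrix.columns if c in set(keep)]
    if len(keep) < min_cells or matrix.shape[1] < min_cells:
        raise ValueError(
            f"need >= {min_cells} cells in both the full and reduced sets"
        )
    params = params or NetworkParams()
    fit_all = CoexpressionNetwork(matrix, params).fit()
    fit_red = CoexpressionNetwork(matrix[keep], params).fit()
    universe = pd.Index(fit_all.gene_universe).intersection(fit_red.gene_universe)
    result = module_overlap(
        fit_all.labels, fit_red.labels, universe, threshold_neglogp
    )
    flagged = sorted(result.specific.index[result.specific], key=str)
    return flagged, result, fit_all, fit_red


def cross_dataset_overlap(
    labels_1: pd.Series,
    labels_2: pd.Series,
    ortholog_map: pd.DataFrame | dict,
    threshold_neglogp: float = 10.0,
) -> OverlapResult:
    """Module overlap between two datasets through an ortholog map.

    ``ortholog_map`` maps dataset-1 gene ids to dataset-2 gene ids
    (two-column frame or dict); many-to-many entries are dropped to
    enforce a 1:1 map. The universe is the mapped genes present in both
    analyses; unmapped genes are dropped with a logged count.
    """
    if isinstance(ortholog_map, dict):
        pairs = pd.DataFrame(
            {"gene_1": list(ortholog_map), "gene_2": list(ortholog_map.values())}
        )
    else:
        pairs = ortholog_map.copy()
        pairs.columns = ["gene_1", "gene_2"]
    pairs = pairs.drop_duplicates()
    pairs = pairs[~pairs["gene_1"].duplicated(keep=False)]
    pairs = pairs[~pairs["gene_2"].duplicated(keep=False)]
    pairs = pairs[
        pairs["gene_1"].isin(labels_1.index) & pairs["gene_2"].isin(labels_2.index)
    ]
    if pairs.empty:
        raise ValueError("ortholog map leaves an empty shared gene universe")
    n_dropped = len(labels_1) - len(pairs)
    if n_dropped:
        warnings.warn(f"{n_dropped} dataset-1 genes not in the 1:1 ortholog map")
    translated = labels_2.reindex(pairs["gene_2"])
    translated.index = pairs["gene_1"].to_numpy()
    return module_overlap(
        labels_1, translated, pd.Index(pairs["gene_1"]), threshold_neglogp
    )
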