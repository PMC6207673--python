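"""Signed weighted co-expression network construction and module detection.

The network follows the weighted co-expression (WGCNA-style) recipe on
log2(RPKM+1) profiles: a signed adjacency ``a_ij = ((1 + r_ij)/2)^beta``
with the soft-threshold power ``beta`` chosen by scale-free topology
fit, topological overlap as the clustering similarity, average-linkage
hierarchical clustering of genes with a recursive fixed-height tree cut,
merging of modules smaller than 30 genes into their closest neighbour by
eigengene correlation, module eigengenes (first principal components of
the standardized module submatrix), module membership (kME), and node
centrality (sum of within-module adjacency) for hub-gene ranking.

The modelling surface is :class:`CoexpressionNetwork` (built from a
genes x cells RPKM matrix) whose :meth:`~CoexpressionNetwork.fit`
returns a :class:`CoexpressionResults` carrying the gene-to-module
assignment, eigengenes, kME, centralities and diagnostics; every step is
also exposed as a module-level function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import log2_rpkm

__all__ = [
    "NetworkParams",
    "CoexpressionNetwork",
    "CoexpressionResults",
    "pick_soft_threshold",
    "build_adjacency",
    "compute_tom",
    "detect_modules",
    "module_eigengene",
    "merge_correlated_modules",
    "clean_module_membership",
    "merge_small_modules",
    "node_centrality",
    "hub_genes",
    "module_correlation",
    "project_eigengenes",
]

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class NetworkParams:
    """Knobs of the network construction.

    ``beta=None`` selects the soft power automatically from
    ``candidate_powers`` as the smallest power whose scale-free topology
    fit reaches ``scale_free_r2_target``. The tree cut severs each
    subtree at ``cut_height_fraction`` x its maximum merge height and
    recurses into branches that split into two or more substantial
    sub-branches; halves of one module that the cut separates are
    rejoined when their eigengenes correlate above
    ``module_merge_corr``, genes with module membership below
    ``min_kme`` are shed, and modules below ``merge_min_genes`` genes
    are merged into their closest larger module.
    """

    beta: int | None = None
    candidate_powers: tuple[int, ...] = tuple(range(1, 21))
    signed: bool = True
    use_tom: bool = True
    cut_height_fraction: float = 0.99
    module_merge_corr: float = 0.9
    min_kme: float = 0.3
    min_module_size: int = 20
    merge_min_genes: int = 30
    scale_free_r2_target: float = 0.8


def _corr_rows(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = int((sd == 0).sum())
        raise ValueError(
            f"{bad} gene(s) have zero variance; filter genes before "
            "building the network (see cardiomod.qc.filter_genes)"
        )
    return np.corrcoef(x)


def pick_soft_threshold(
    log_expr: pd.DataFrame,
    candidate_powers=tuple(range(1, 21)),
    signed: bool = True,
    scale_free_r2_target: float = 0.8,
    n_bins: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Choose the soft-threshold power by scale-free topology fit.

    For each candidate power the whole-network connectivities
    ``k_i = sum_j a_ij`` are binned (equal-width), and the signed fit
    ``-sign(slope) * R^2`` of the regression of log10 p(k) on log10 k
    is computed. Returns the smallest power reaching the target fit
    (else the power maximizing it) and the full fit table.
    """
    if log_expr.shape[0] < 20 or log_expr.shape[1] < 10:
        raise ValueError("need >= 20 genes and >= 10 cells to estimate beta")
    corr = _corr_rows(log_expr.to_numpy())
    base = (1.0 + corr) / 2.0 if signed else np.abs(corr)
    rows = []
    for power in candidate_powers:
        adj = base**power
        np.fill_diagonal(adj, 0.0)
        k = adj.sum(axis=1)
        fit, slope = _scale_free_fit(k, n_bins=n_bins)
        rows.append(
            {
                "power": power,
                "sft_r2": fit,
                "slope": slope,
                "mean_k": float(k.mean()),
                "median_k": float(np.median(k)),
                "max_k": float(k.max()),
            }
        )
    table = pd.DataFrame(rows).set_index("power")
    if table["sft_r2"].isna().all():
        raise ValueError(
            "scale-free fit undefined for every candidate power "
            "(degenerate correlation structure)"
        )
    ok = table.index[table["sft_r2"] >= scale_free_r2_target]
    beta = int(ok[0]) if len(ok) else int(table["sft_r2"].idxmax())
    return beta, table


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed R^2 of log10 p(k) ~ log10 k over equal-width k bins."""
    k = k[k > 0]
    if len(k) < n_bins or np.ptp(k) == 0:
        return float("nan"), float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_k, log_p = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        log_k.append(np.log10(k[mask].mean()))
        log_p.append(np.log10(mask.mean()))
    if len(log_k) < 3 or np.ptp(log_k) == 0:
        return float("nan"), float("nan")
    slope, intercept = np.polyfit(log_k, log_p, 1)
    pred = slope * np.asarray(log_k) + intercept
    resid = np.asarray(log_p) - pred
    ss_tot = float(((np.asarray(log_p) - np.mean(log_p)) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else float("nan")
    return -np.sign(slope) * r2, float(slope)


def build_adjacency(
    log_expr: pd.DataFrame, beta: int, signed: bool = True
) -> pd.DataFrame:
    """Signed adjacency ``a_ij = ((1 + r_ij)/2)^beta`` with unit diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    corr = _corr_rows(log_expr.to_numpy())
    base = (1.0 + corr) / 2.0 if signed else np.abs(corr)
    adj = np.clip(base, 0.0, 1.0) ** beta
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=log_expr.index, columns=log_expr.index)


def compute_tom(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap ``w_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij)``.

    ``l_ij = sum_{u != i,j} a_iu a_uj`` and ``k_i = sum_{u != i} a_iu``;
    the diagonal is 1. ``1 - w`` is the clustering dissimilarity.
    """
    a = adjacency.to_numpy(dtype=float)
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    # (A @ A)_ij = sum_u a_iu a_uj already excludes u = i, j because the
    # working diagonal is zeroed.
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (shared + a) / denom
    tom[~np.isfinite(tom)] = 0.0
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def detect_modules(
    dissimilarity: pd.DataFrame,
    min_module_size: int = 20,
    cut_height_fraction: float = 0.99,
) -> pd.Series:
    """Average-linkage clustering of genes with a recursive fixed-height cut.

    Each subtree's dendrogram is cut at ``cut_height_fraction`` x its
    own maximum merge height (severing at least the top merge). When
    the cut yields two or more branches of at least ``min_module_size``
    genes the split is treated as real and each branch is re-cut
    recursively; when at most one substantial branch remains, the
    subtree is kept whole as a module. Diffuse background genes scatter
    into fragments below the size floor and end up unassigned (-1).
    A tight module that the fixed-height cut happens to halve comes out
    as two modules here; :func:`merge_correlated_modules` rejoins such
    halves by eigengene correlation, and attached background genes are
    shed afterwards by kME cleanup (:func:`clean_module_membership`).
    Module ids are renumbered by size, largest first.
    """
    d = dissimilarity.to_numpy(dtype=float)
    if (d < -1e-9).any() or (d > 1 + 1e-9).any():
        raise ValueError("dissimilarity values must lie in [0, 1]")
    if not 0.0 < cut_height_fraction < 1.0:
        raise ValueError("cut_height_fraction must lie in (0, 1)")
    n = d.shape[0]
    labels = np.full(n, -1, dtype=int)
    if n < min_module_size:
        warnings.warn("fewer genes than min_module_size; all genes unassigned")
        return pd.Series(labels, index=dissimilarity.index, name="module")
    counter = [0]

    def assign(idx: np.ndarray) -> None:
        labels[idx] = counter[0]
        counter[0] += 1

    def recurse(idx: np.ndarray) -> None:
        sub = d[np.ix_(idx, idx)].copy()
        np.fill_diagonal(sub, 0.0)
        z = linkage(squareform(sub, checks=False), method="average")
        h_max = float(z[:, 2].max())
        if h_max <= 0:  # identical profiles
            assign(idx)
            return
        cl = fcluster(z, t=cut_height_fraction * h_max, criterion="distance")
        children = [idx[cl == c] for c in range(1, cl.max() + 1)]
        substantial = [c for c in children if len(c) >= min_module_size]
        if len(substantial) <= 1:
            assign(idx)  # no real split: keep the branch whole
            return
        for child in substantial:
            recurse(child)

    recurse(np.arange(n))
    # renumber by size descending, ties by smallest member index
    sizes = pd.Series(labels[labels >= 0]).value_counts()
    order = sorted(
        sizes.index, key=lambda m: (-sizes[m], int(np.argmax(labels == m)))
    )
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap.get(v, -1) for v in labels])
    return pd.Series(labels, index=dissimilarity.index, name="module")


def module_eigengene(
    log_expr: pd.DataFrame, labels: pd.Series
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """First principal component of each module's standardized submatrix.

    Eigengenes are unit-norm profiles over cells, sign-oriented so the
    average correlation with member genes is positive. Returns
    (eigengene matrix modules x cells, variance explained, projection
    parameters for scoring new cells with the same weights).
    """
    labels = labels.reindex(log_expr.index)
    eig, var_exp, proj = {}, {}, {}
    for mod in _module_ids(labels):
        genes = labels.index[labels == mod]
        x = log_expr.loc[genes].to_numpy(dtype=float)
        if len(genes) == 1:
            warnings.warn(f"module {mod} has a single gene; eigengene is its profile")
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = (x - mu) / sd
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        e = vt[0]
        w = u[:, 0]
        if (z @ e).mean() < 0:  # orient: mean member correlation positive
            e, w = -e, -w
        eig[mod] = e
        var_exp[mod] = float(s[0] ** 2 / (s**2).sum()) if (s**2).sum() > 0 else 0.0
        proj[mod] = {
            "genes": list(genes),
            "mean": mu.ravel(),
            "sd": sd.ravel(),
            "weights": w,
            "singular_value": float(s[0]),
        }
    eigengenes = pd.DataFrame(eig, index=log_expr.columns).T
    eigengenes.index.name = "module"
    return eigengenes, pd.Series(var_exp, name="variance_explained"), proj


def _module_ids(labels: pd.Series) -> list:
    return sorted(v for v in pd.unique(labels.dropna()) if v != -1 and v != UNASSIGNED)


def merge_correlated_modules(
    log_expr: pd.DataFrame,
    labels: pd.Series,
    corr_threshold: float = 0.9,
) -> pd.Series:
    """Iteratively merge the module pair with the highest eigengene
    correlation while it exceeds ``corr_threshold``.

    Rejoins module halves separated by the fixed-height cut: halves of
    one co-expression program share the latent profile (eigengene
    correlation near 1), whereas distinct programs correlate far below
    the threshold. Ties break lexicographically; the smaller label wins.
    """
    labels = labels.copy()
    while True:
        mods = _module_ids(labels)
        if len(mods) < 2:
            break
        eigengenes, _, _ = module_eigengene(log_expr, labels)
        e = eigengenes.loc[mods].to_numpy()
        corr = np.corrcoef(e)
        np.fill_diagonal(corr, -np.inf)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] < corr_threshold:
            break
        keep, drop = sorted([mods[i], mods[j]], key=str)
        labels[labels == drop] = keep
    return labels


def clean_module_membership(
    log_expr: pd.DataFrame,
    labels: pd.Series,
    min_kme: float = 0.3,
    min_module_size: int = 20,
) -> pd.Series:
    """Shed genes whose module membership (kME) falls below ``min_kme``.

    Each module's eigengene is recomputed and member genes correlating
    with it below the floor are unassigned; modules dropping below
    ``min_module_size`` genes are dissolved entirely. One pass per
    module (recomputation after shedding changes little and keeps the
    operation deterministic and cheap).
    """
    labels = labels.copy()
    eigengenes, _, _ = module_eigengene(log_expr, labels)
    for mod in _module_ids(labels):
        genes = labels.index[labels == mod]
        x = log_expr.loc[genes].to_numpy(dtype=float)
        e = eigengenes.loc[mod].to_numpy(dtype=float)
        xc = x - x.mean(axis=1, keepdims=True)
        ec = e - e.mean()
        denom = np.sqrt((xc**2).sum(axis=1)) * np.sqrt((ec**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            kme = (xc @ ec) / denom
        keep = kme >= min_kme
        labels[genes[~keep]] = -1
        if keep.sum() < min_module_size:
            labels[genes[keep]] = -1
    return labels


def merge_small_modules(
    log_expr: pd.DataFrame,
    labels: pd.Series,
    merge_min_genes: int = 30,
) -> pd.Series:
    """Merge modules with fewer than ``merge_min_genes`` genes into their
    closest larger module by eigengene correlation.

    Modules are processed smallest first (ties by label); candidate
    targets are modules already at or above the size floor. When no
    module reaches the floor, everything is merged into the single
    largest module with a warning. Eigengenes are recomputed after each
    merge.
    """
    labels = labels.copy()
    while True:
        sizes = labels[labels != -1].value_counts()
        small = sizes[sizes < merge_min_genes]
        if small.empty or len(sizes) < 2:
            break
        large = sizes[sizes >= merge_min_genes]
        eigengenes, _, _ = module_eigengene(log_expr, labels)
        mod = sorted(small.index, key=lambda m: (small[m], m))[0]
        if large.empty:
            target = sizes.idxmax()
            warnings.warn(
                "no module reaches the merge size floor; merging into the "
                "largest module"
            )
        else:
            corr = {
                other: float(np.corrcoef(eigengenes.loc[mod], eigengenes.loc[other])[0, 1])
                for other in large.index
                if other != mod
            }
            if not corr:
                break
            target = max(sorted(corr), key=lambda m: corr[m])
        labels[labels == mod] = target
    return labels


def node_centrality(adjacency: pd.DataFrame, labels: pd.Series) -> pd.Series:
    """Within-module connectivity: sum of adjacency to same-module genes.

    Unassigned genes get centrality 0.
    """
    labels = labels.reindex(adjacency.index)
    a = adjacency.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    cent = np.zeros(len(labels))
    for mod in _module_ids(labels):
        mask = (labels == mod).to_numpy()
        cent[mask] = a[np.ix_(mask, mask)].sum(axis=1)
    return pd.Series(cent, index=adjacency.index, name="centrality")


def hub_genes(
    centrality: pd.Series, labels: pd.Series, top_n: int = 5
) -> dict:
    """Top-``top_n`` genes per module by within-module connectivity."""
    out = {}
    for mod in _module_ids(labels):
        genes = labels.index[labels == mod]
        ranked = centrality.loc[genes].sort_values(ascending=False)
        out[mod] = list(ranked.index[:top_n])
    return out


def module_correlation(eigengenes: pd.DataFrame) -> pd.DataFrame:
    """Module-to-module Pearson correlation of eigengene profiles."""
    if eigengenes.shape[1] < 3:
        raise ValueError("need at least 3 cells")
    corr = np.corrcoef(eigengenes.to_numpy())
    return pd.DataFrame(corr, index=eigengenes.index, columns=eigengenes.index)


def project_eigengenes(
    new_log_expr: pd.DataFrame, projection: dict
) -> tuple[pd.DataFrame, dict[object, bool]]:
    """Score new cells on reference modules with the reference weights.

    Genes are standardized with the reference per-gene mean/sd; missing
    genes are imputed at z = 0 with a warning. Modules with < 50% of
    their genes present are flagged unreliable (second return value);
    a module with no genes present raises.
    """
    scores, flags = {}, {}
    for mod, ref in projection.items():
        genes = pd.Index(ref["genes"])
        present = genes.intersection(new_log_expr.index)
        if len(present) == 0:
            raise ValueError(f"no genes of module {mod} present in the new matrix")
        frac = len(present) / len(genes)
        flags[mod] = frac < 0.5
        if frac < 1.0:
            warnings.warn(
                f"module {mod}: {len(genes) - len(present)} of {len(genes)} "
                "genes absent; imputed at z=0"
            )
        z = np.zeros((len(genes), new_log_expr.shape[1]))
        pos = {g: i for i, g in enumerate(genes)}
        rows = [pos[g] for g in present]
        x = new_log_expr.loc[present].to_numpy(dtype=float)
        mean = np.asarray(ref["mean"])[rows][:, None]
        sd = np.asarray(ref["sd"])[rows][:, None]
        z[rows] = (x - mean) / sd
        s = ref["singular_value"]
        scores[mod] = (z.T @ np.asarray(ref["weights"])) / (s if s > 0 else 1.0)
    out = pd.DataFrame(scores, index=new_log_expr.columns).T
    out.index.name = "module"
    return out, flags


class CoexpressionNetwork:
    """Signed weighted co-expression network model of an expression matrix.

    Parameters
    ----------
    expression
        Genes x cells matrix on the RPKM scale (non-negative). The
        network is computed on log2(RPKM+1) unless ``log_transform``
        is False (in which case the matrix is used as-is).
    params
        :class:`NetworkParams`; defaults follow the signed-network
        recipe with automatic power selection.
    """

    def __init__(
        self,
        expression: pd.DataFrame,
        params: NetworkParams | None = None,
        log_transform: bool = True,
    ):
        self.params = params or NetworkParams()
        self.log_expr = log2_rpkm(expression) if log_transform else expression.copy()
        sd = self.log_expr.std(axis=1)
        n_const = int((sd == 0).sum())
        if n_const:
            warnings.warn(f"dropping {n_const} zero-variance gene(s)")
            self.log_expr = self.log_expr.loc[sd > 0]

    @classmethod
    def from_dataframe(cls, expression: pd.DataFrame, **kwargs) -> "CoexpressionNetwork":
        return cls(expression, **kwargs)

    def fit(self) -> "CoexpressionResults":
        p = self.params
        if p.beta is None:
            beta, power_table = pick_soft_threshold(
                self.log_expr, p.candidate_powers, p.signed, p.scale_free_r2_target
            )
        else:
            beta, power_table = int(p.beta), None
        adjacency = build_adjacency(self.log_expr, beta, p.signed)
        if p.use_tom:
            dissim = 1.0 - compute_tom(adjacency)
        else:
            dissim = 1.0 - adjacency
        labels = detect_modules(dissim, p.min_module_size, p.cut_height_fraction)
        labels = merge_correlated_modules(self.log_expr, labels, p.module_merge_corr)
        labels = clean_module_membership(
            self.log_expr, labels, p.min_kme, p.min_module_size
        )
        labels = merge_small_modules(self.log_expr, labels, p.merge_min_genes)
        eigengenes, var_exp, projection = module_eigengene(self.log_expr, labels)
        centrality = node_centrality(adjacency, labels)
        return CoexpressionResults(
            params=replace(p, beta=beta),
            power_table=power_table,
            labels=_relabel(labels),
            eigengenes=_relabel_index(eigengenes, labels),
            variance_explained=_relabel_series(var_exp, labels),
            kme=_kme(self.log_expr, eigengenes, labels),
            centrality=centrality,
            projection=_relabel_keys(projection, labels),
            gene_universe=list(self.log_expr.index),
        )


def _size_rank(labels: pd.Series) -> dict:
    """Map internal module ids to 'M1', 'M2', ... by size descending."""
    sizes = labels[labels != -1].value_counts()
    order = sorted(sizes.index, key=lambda m: (-sizes[m], str(m)))
    return {old: f"M{i + 1}" for i, old in enumerate(order)}


def _relabel(labels: pd.Series) -> pd.Series:
    names = _size_rank(labels)
    return labels.map(lambda v: names.get(v, UNASSIGNED)).rename("module")


def _relabel_index(df: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    names = _size_rank(labels)
    out = df.rename(index=names)
    return out.loc[sorted(out.index, key=lambda m: int(m[1:]))]


def _relabel_series(s: pd.Series, labels: pd.Series) -> pd.Series:
    names = _size_rank(labels)
    out = s.rename(index=names)
    return out.loc[sorted(out.index, key=lambda m: int(m[1:]))]


def _relabel_keys(d: dict, labels: pd.Series) -> dict:
    names = _size_rank(labels)
    return {names[k]: v for k, v in d.items()}


def _kme(log_expr: pd.DataFrame, eigengenes: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    names = _size_rank(labels)
    e = _relabel_index(eigengenes, labels)
    x = log_expr.to_numpy(dtype=float)
    xz = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    em = e.to_numpy(dtype=float)
    ez = (em - em.mean(axis=1, keepdims=True)) / em.std(axis=1, keepdims=True)
    kme = xz @ ez.T / x.shape[1]
    return pd.DataFrame(kme, index=log_expr.index, columns=e.index)


@dataclass
class CoexpressionResults:
    """Fitted co-expression network: modules, eigengenes and diagnostics.

    Modules are named M1, M2, ... by decreasing size; genes in no module
    carry the label ``"unassigned"``. ``eigengenes`` is modules x cells
    (unit-norm profiles); ``kme`` is genes x modules; ``centrality`` is
    the within-module connectivity per gene.
    """

    params: NetworkParams
    power_table: pd.DataFrame | None
    labels: pd.Series
    eigengenes: pd.DataFrame
    variance_explained: pd.Series
    kme: pd.DataFrame
    centrality: pd.Series
    projection: dict
    gene_universe: list = field(default_factory=list)

    @property
    def module_sizes(self) -> pd.Series:
        sizes = self.labels[self.labels != UNASSIGNED].value_counts()
        return sizes.loc[sorted(sizes.index, key=lambda m: int(m[1:]))]

    @property
    def n_modules(self) -> int:
        return int(len(self.module_sizes))

    def module_genes(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])

    def hub_genes(self, top_n: int = 5) -> dict:
        return hub_genes(self.centrality, self.labels, top_n)

    def module_correlation(self) -> pd.DataFrame:
        return module_correlation(self.eigengenes)

    def project(
        self, expression: pd.DataFrame, log_transform: bool = True
    ) -> pd.DataFrame:
        """Eigengene scores for additional cells using the fitted weights."""
        x = log2_rpkm(expression) if log_transform else expression
        scores, flags = project_eigengenes(x, self.projection)
        unreliable = [m for m, bad in flags.items() if bad]
        if unreliable:
            warnings.warn(f"projection unreliable for modules: {unreliable}")
        return scores

    def summary(self) -> pd.DataFrame:
        """Per-module table: size, variance explained, top hub gene."""
        hubs = self.hub_genes(top_n=1)
        rows = []
        for mod, size in self.module_sizes.items():
            rows.append(
                {
                    "module": mod,
                    "n_genes": int(size),
                    "variance_explained": float(self.variance_explained[mod]),
                    "hub_gene": hubs[mod][0] if hubs.get(mod) else "",
                }
            )
        df = pd.DataFrame(rows).set_index("module")
        df.attrs["beta"] = self.params.beta
        df.attrs["n_unassigned"] = int((self.labels == UNASSIGNED).sum())
        return df

    def plot_eigengenes(self, ax=None):
        """Heatmap of module eigengene activity across cells."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 0.4 * max(len(self.eigengenes), 4) + 1))
        im = ax.imshow(self.eigengenes.to_numpy(), aspect="auto", cmap="RdBu_r")
        ax.set_yticks(range(len(self.eigengenes)), self.eigengenes.index)
        ax.set_xlabel("cells")
        ax.set_ylabel("module eigengene")
        ax.figure.colorbar(im, ax=ax, label="eigengene value")
        return ax
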