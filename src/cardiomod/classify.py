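"""Module-based cell classification with Random-Forests model selection.

Cells are clustered on their module eigengene profiles (hierarchical,
correlation distance, complete linkage, minimum cluster size 5% of
cells), classification-significant modules are selected with a
shadow-feature Random-Forests criterion, the cluster number is chosen
from an out-of-bag error sweep over k = 4..10, and new cells are
allocated to the predetermined clusters by a forest trained on the
reference cells. Group-by-cluster composition differences are assessed
with Fisher's exact test (exact enumeration for small tables).

:class:`ModuleClassifier` is the model-object surface; each step is
also a module-level function.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import random_table
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "ModuleClassifier",
    "ClassificationResults",
    "cluster_cells",
    "rf_select_modules",
    "error_rate_sweep",
    "allocate_cells",
    "composition_test",
    "embed_cells",
]

N_TREES = 1000  # forest size; large enough for stable importance ranks


def _corr_distance(x: np.ndarray) -> np.ndarray:
    """1 - Pearson r between rows, clipped into [0, 2]."""
    sd = x.std(axis=1)
    if (sd == 0).any():
        raise ValueError("cells with zero feature variance cannot be clustered")
    return np.clip(1.0 - np.corrcoef(x), 0.0, 2.0)


def cluster_cells(
    features: pd.DataFrame,
    k: int,
    min_cluster_fraction: float = 0.05,
) -> pd.Series:
    """Hierarchical clustering of cells (rows = cells, columns = modules).

    Complete linkage on correlation distance, cut to ``k`` groups;
    clusters smaller than ``ceil(min_cluster_fraction * n)`` are
    dissolved into the surviving cluster whose centroid correlates best
    with theirs (rule waived for n < 20). Labels are renumbered 1..K by
    size, largest first.
    """
    n = features.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k = {k} exceeds the number of cells ({n})")
    d = _corr_distance(features.to_numpy(dtype=float))
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="complete")
    labels = fcluster(z, t=k, criterion="maxclust")

    min_size = math.ceil(min_cluster_fraction * n)
    if n < 20:
        min_size = 1
    x = features.to_numpy(dtype=float)
    while True:
        sizes = pd.Series(labels).value_counts()
        small = sizes[sizes < min_size]
        surviving = sizes[sizes >= min_size]
        if small.empty or surviving.empty:
            break
        c = small.index[np.argmin(small.to_numpy())]
        centroid = x[labels == c].mean(axis=0)
        best, best_r = None, -np.inf
        for s in sorted(surviving.index):
            r = np.corrcoef(centroid, x[labels == s].mean(axis=0))[0, 1]
            if r > best_r:
                best, best_r = s, r
        labels[labels == c] = best

    sizes = pd.Series(labels).value_counts()
    first_member = {c: int(np.argmax(labels == c)) for c in sizes.index}
    order = sorted(sizes.index, key=lambda c: (-sizes[c], first_member[c]))
    remap = {old: i + 1 for i, old in enumerate(order)}
    out = np.array([remap[v] for v in labels])
    return pd.Series(out, index=features.index, name="cluster")


def rf_select_modules(
    eigengenes: pd.DataFrame,
    labels: pd.Series,
    seed: int = 0,
    n_repeats: int = 11,
    n_trees: int = N_TREES,
    hit_threshold: float = 0.9,
) -> tuple[list, pd.DataFrame]:
    """Select classification-significant modules with shadow features.

    ``eigengenes`` is cells x modules. In each of ``n_repeats`` seeded
    rounds, a permuted (shadow) copy of every module is appended and a
    forest predicts the cluster labels; a module scores a hit when its
    impurity importance exceeds the maximum shadow importance of that
    round. Modules are selected when they dominate the shadows in at
    least ``hit_threshold`` of the rounds: informative modules beat
    every shadow essentially always, whereas a noise module that
    correlates with the labels by chance trades places with the shadow
    maximum from round to round.
    Returns (selected module ids, importance table with hit fractions).
    """
    labels = labels.reindex(eigengenes.index)
    if labels.nunique() < 2:
        raise ValueError("need at least 2 clusters to select modules")
    x = eigengenes.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    n, m = x.shape
    hits = np.zeros(m)
    imps = np.zeros(m)
    for rep in range(n_repeats):
        shadow = np.empty_like(x)
        for j in range(m):
            shadow[:, j] = x[rng.permutation(n), j]
        forest = RandomForestClassifier(
            n_estimators=n_trees,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        forest.fit(np.hstack([x, shadow]), labels.to_numpy())
        imp = forest.feature_importances_
        real, decoy = imp[:m], imp[m:]
        hits += real > decoy.max()
        imps += real
    table = pd.DataFrame(
        {
            "importance": imps / n_repeats,
            "hit_fraction": hits / n_repeats,
        },
        index=eigengenes.columns,
    ).sort_values("importance", ascending=False)
    selected = [
        m_ for m_ in eigengenes.columns
        if table.loc[m_, "hit_fraction"] >= hit_threshold
    ]
    return selected, table


def error_rate_sweep(
    features: pd.DataFrame,
    k_range=range(4, 11),
    seed: int = 0,
    drastic_factor: float = 2.0,
    min_cluster_fraction: float = 0.0,
    n_trees: int = N_TREES,
) -> tuple[pd.Series, int]:
    """Out-of-bag error of a forest predicting k-cluster labels, per k.

    The sweep evaluates the raw k-group cuts of the dendrogram
    (``min_cluster_fraction=0``): dissolving sub-floor clusters inside
    the sweep would make the labels beyond the true cluster number
    identical to those at it, flattening the very error increase the
    sweep is looking for. The 5%-floor rule is applied to the final
    clustering at the chosen k instead.

    The chosen k is the edge of the low plateau of the error curve:
    the largest k whose error is below ``drastic_factor`` x the error
    floor while the next k's error is not (the "last k before the
    drastic increase"). The floor is the minimum error over
    the range, but never below 2 cells' worth of error, so that
    near-zero plateaus do not turn one-cell fluctuations into
    "drastic" increases. When the curve never leaves the plateau (no
    drastic increase anywhere) the error carries no evidence for extra
    clusters and the smallest k within two cells' error of the minimum
    is returned.
    """
    errors = {}
    x = features.to_numpy(dtype=float)
    for k in k_range:
        labels = cluster_cells(features, k, min_cluster_fraction)
        forest = RandomForestClassifier(
            n_estimators=n_trees, oob_score=True, random_state=seed, n_jobs=1
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # few-OOB-sample warnings at tiny n
            forest.fit(x, labels.to_numpy())
        errors[k] = 1.0 - float(forest.oob_score_)
    errors = pd.Series(errors, name="oob_error")
    floor = max(errors.min(), 2.0 / features.shape[0])
    thr = drastic_factor * floor * (1.0 - 1e-9)  # errors at exactly 2x count as drastic
    chosen = None
    ks = list(errors.index)
    for i, k in enumerate(ks):
        low = errors[k] < thr
        nxt_high = i + 1 >= len(ks) or errors[ks[i + 1]] >= thr
        if low and nxt_high:
            chosen = int(k)
            break  # first edge: "before the first drastic increase"
    if chosen is None:
        tol = errors.min() + 2.0 / features.shape[0]
        chosen = int(errors.index[errors <= tol][0])
    return errors, chosen


def allocate_cells(
    reference_features: pd.DataFrame,
    reference_labels: pd.Series,
    new_features: pd.DataFrame,
    seed: int = 0,
    n_trees: int = N_TREES,
) -> tuple[pd.Series, pd.DataFrame]:
    """Allocate new cells to predetermined clusters with a Random Forest.

    The forest is trained on the reference cells' selected-module
    eigengene values; returns per-cell assignments and vote fractions.
    """
    if list(new_features.columns) != list(reference_features.columns):
        raise ValueError(
            "new feature columns do not match the reference modules: "
            f"{list(new_features.columns)} vs {list(reference_features.columns)}"
        )
    if new_features.empty:
        return (
            pd.Series([], dtype=int, name="cluster"),
            pd.DataFrame(columns=sorted(reference_labels.unique())),
        )
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    forest.fit(
        reference_features.to_numpy(dtype=float),
        reference_labels.reindex(reference_features.index).to_numpy(),
    )
    votes = forest.predict_proba(new_features.to_numpy(dtype=float))
    vote_df = pd.DataFrame(votes, index=new_features.index, columns=forest.classes_)
    assigned = pd.Series(
        forest.predict(new_features.to_numpy(dtype=float)),
        index=new_features.index,
        name="cluster",
    )
    return assigned, vote_df


# ---------------------------------------------------------------------------
# Fisher's exact test for r x c composition tables


def _table_log_prob(table: np.ndarray, log_fact: np.ndarray) -> float:
    """log P(table | margins) under the multiple hypergeometric law."""
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    return (
        log_fact[r].sum()
        + log_fact[c].sum()
        - log_fact[n]
        - log_fact[table].sum()
    )


def _enumerate_pvalue(table: np.ndarray) -> float:
    """Exact two-sided Fisher p for an r x c table by full enumeration."""
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = int(table.sum())
    log_fact = np.concatenate([[0.0], np.cumsum(np.log(np.arange(1, n + 1)))])
    obs = _table_log_prob(table, log_fact)
    total = 0.0

    def rec(i: int, remaining_cols: np.ndarray, partial: list):
        nonlocal total
        if i == len(rows) - 1:
            last = remaining_cols
            if (last < 0).any():
                return
            t = np.array(partial + [last])
            lp = _table_log_prob(t, log_fact)
            if lp <= obs + 1e-9:
                total += math.exp(lp)
            return
        # enumerate compositions of row i over columns
        def fill(j: int, left: int, row: list):
            if j == len(cols) - 1:
                if left <= remaining_cols[j]:
                    rec(i + 1, remaining_cols - np.array(row + [left]),
                        partial + [np.array(row + [left])])
                return
            for v in range(min(left, remaining_cols[j]) + 1):
                fill(j + 1, left - v, row + [v])

        fill(0, int(rows[i]), [])

    rec(0, cols.copy(), [])
    return min(total, 1.0)


def composition_test(
    assignments: pd.Series,
    group_labels: pd.Series,
    max_exact_total: int = 60,
    n_monte_carlo: int = 100_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, float, str]:
    """Fisher's exact test of cluster composition between groups.

    Builds the group x cluster contingency table and computes the
    two-sided exact p by full enumeration over all tables with the
    observed margins when the total count is small, falling back to
    seeded Monte-Carlo sampling (Patefield's algorithm) otherwise.
    Returns (table, p, method).
    """
    group_labels = group_labels.reindex(assignments.index)
    table = pd.crosstab(group_labels, assignments)
    if table.size == 0 or table.to_numpy().sum() == 0:
        raise ValueError("empty contingency table")
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need >= 2 groups and >= 2 clusters")
    t = table.to_numpy(dtype=int)
    if t.sum() <= max_exact_total:
        return table, _enumerate_pvalue(t), "exact"
    rng = np.random.default_rng(seed)
    log_fact = np.concatenate(
        [[0.0], np.cumsum(np.log(np.arange(1, t.sum() + 1)))]
    )
    obs = _table_log_prob(t, log_fact)
    samples = random_table(t.sum(axis=1), t.sum(axis=0)).rvs(
        n_monte_carlo, method="patefield", random_state=rng
    )
    lp = np.array(
        [_table_log_prob(s.astype(int), log_fact) for s in samples]
    )
    p = (1.0 + (lp <= obs + 1e-9).sum()) / (n_monte_carlo + 1.0)
    return table, float(p), "monte-carlo"


def embed_cells(
    eigengenes: pd.DataFrame, perplexity: float = 10.0, seed: int = 0
) -> pd.DataFrame:
    """2-D t-SNE embedding of cells from module eigengene profiles.

    Reporting-only convenience; requires >= 3 x perplexity cells.
    """
    n = eigengenes.shape[0]
    if n < 3 * perplexity:
        raise ValueError(
            f"need at least {math.ceil(3 * perplexity)} cells for "
            f"perplexity {perplexity} (got {n})"
        )
    from sklearn.manifold import TSNE

    coords = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca"
    ).fit_transform(eigengenes.to_numpy(dtype=float))
    return pd.DataFrame(coords, index=eigengenes.index, columns=["tsne1", "tsne2"])


class ModuleClassifier:
    """Cell classification model on module eigengene profiles.

    Built from a cells x modules eigengene matrix; :meth:`fit` selects
    significant modules (shadow-feature Random Forests), sweeps the
    cluster number over ``k_range`` and returns a
    :class:`ClassificationResults` with the reference clustering and
    the allocation forest inputs.
    """

    def __init__(
        self,
        eigengenes: pd.DataFrame,
        k_range=range(4, 11),
        seed: int = 0,
        min_cluster_fraction: float = 0.05,
        drastic_factor: float = 2.0,
    ):
        if eigengenes.ndim != 2 or eigengenes.empty:
            raise ValueError("eigengenes must be a non-empty cells x modules frame")
        self.eigengenes = eigengenes
        self.k_range = list(k_range)
        self.seed = seed
        self.min_cluster_fraction = min_cluster_fraction
        self.drastic_factor = drastic_factor

    @classmethod
    def from_results(cls, results, **kwargs) -> "ModuleClassifier":
        """Build from a fitted :class:`~cardiomod.network.CoexpressionResults`."""
        return cls(results.eigengenes.T, **kwargs)

    def fit(self) -> "ClassificationResults":
        errors, chosen_k = error_rate_sweep(
            self.eigengenes,
            self.k_range,
            seed=self.seed,
            drastic_factor=self.drastic_factor,
            min_cluster_fraction=0.0,  # raw cuts in the sweep; 5% floor below
        )
        labels = cluster_cells(self.eigengenes, chosen_k, self.min_cluster_fraction)
        selected, importance = rf_select_modules(
            self.eigengenes, labels, seed=self.seed
        )
        return ClassificationResults(
            selected_modules=selected,
            labels=labels,
            importance=importance,
            error_rates=errors,
            chosen_k=chosen_k,
            features=self.eigengenes[selected] if selected else self.eigengenes,
            seed=self.seed,
        )


@dataclass
class ClassificationResults:
    """Reference clustering, selected modules and the allocation inputs."""

    selected_modules: list
    labels: pd.Series
    importance: pd.DataFrame
    error_rates: pd.Series
    chosen_k: int
    features: pd.DataFrame
    seed: int = 0
    min_cluster_fraction: float = 0.05

    def allocate(self, new_eigengenes: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
        """Assign new cells (cells x modules) to the reference clusters."""
        cols = self.features.columns
        missing = [c for c in cols if c not in new_eigengenes.columns]
        if missing:
            raise ValueError(f"new eigengenes missing modules: {missing}")
        return allocate_cells(
            self.features, self.labels, new_eigengenes[cols], seed=self.seed
        )

    def composition_test(self, group_labels: pd.Series, **kwargs):
        return composition_test(self.labels, group_labels, **kwargs)

    def embed(self, perplexity: float = 10.0) -> pd.DataFrame:
        return embed_cells(self.features, perplexity, seed=self.seed)

    def summary(self) -> pd.DataFrame:
        """Per-k error table plus cluster sizes at the chosen k."""
        df = self.error_rates.to_frame()
        df["chosen"] = df.index == self.chosen_k
        df.attrs["selected_modules"] = list(self.selected_modules)
        df.attrs["cluster_sizes"] = self.labels.value_counts().to_dict()
        return df

    def to_dict(self) -> dict:
        """JSON-serializable model state (forest refit from seed on load)."""
        return {
            "selected_modules": list(self.selected_modules),
            "labels": {str(k): int(v) for k, v in self.labels.items()},
            "chosen_k": self.chosen_k,
            "seed": self.seed,
            "error_rates": {int(k): float(v) for k, v in self.error_rates.items()},
        }
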