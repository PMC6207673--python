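"""Synthetic single-cardiomyocyte expression data with planted structure.

The generator emulates the statistical features of a pressure-overload
single-cardiomyocyte RNA-seq experiment on an RPKM-like scale: a few
hundred cells sampled over six stages (sham, day 3, weeks 1/2/4/8),
latent-factor co-expression modules of varying size, cell clusters
defined by which modules are active at each stage, one module active in
only a fraction of the cells of a single stage, and a per-cell area
covariate (um^2) coupled to one module's factor.

Model (log2 scale): ``x_gc = b_g + sum_m L_gm * f_mc + eps_gc`` with
``eps ~ N(0, noise_sd)``, loadings ``L_gm ~ N(loading_mean, loading_sd)``
for genes in module m (0 otherwise), and factors
``f_mc ~ N(stage_activity[m, stage(c)], 1)``. The stage-specific module's
factor is nonzero only for a Bernoulli(active_fraction) subset of its
stage's cells, so its co-expression signal vanishes when that stage is
removed. The reported matrix is ``2^x - 1`` clipped at zero, with
dropouts set to zero at a magnitude-independent rate.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as _io

__all__ = [
    "ModuleSpec",
    "SimConfig",
    "SimTruth",
    "default_config",
    "module_recovery_config",
    "stage_specific_config",
    "seven_cluster_config",
    "morphology_config",
    "simulate_cells",
    "write_dataset",
    "read_dataset",
]

#: Stage labels of the pressure-overload time course (sham + 5 post-TAC times).
DEFAULT_STAGES = ("sham", "d3", "w1", "w2", "w4", "w8")

#: Cells per stage mirroring the profiled cohort (396 cells total).
DEFAULT_CELLS_PER_STAGE = {
    "sham": 64, "d3": 58, "w1": 82, "w2": 61, "w4": 73, "w8": 58,
}


@dataclass(frozen=True)
class ModuleSpec:
    """Size and loading distribution of one planted co-expression module."""

    size: int
    loading_mean: float = 1.0
    loading_sd: float = 0.3


@dataclass
class SimConfig:
    """Configuration of the planted-structure generator.

    ``stage_activity`` is a (modules x stages) array of per-stage factor
    means; its distinct realized rows define the ground-truth cell
    clusters. ``stage_specific_module`` is ``(module_index, stage_label,
    active_fraction)``: that module's factor is drawn around its stage
    mean for a Bernoulli(active_fraction) subset of the named stage's
    cells and is zero elsewhere. ``area_coupling`` is ``(module_index,
    alpha, area_noise_sd, area_baseline)`` with
    ``area = baseline + alpha * f * baseline/10 + N(0, area_noise_sd)``.
    """

    n_genes: int = 10_000
    n_cells_per_stage: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CELLS_PER_STAGE)
    )
    modules: list[ModuleSpec] = field(default_factory=list)
    stage_activity: np.ndarray | None = None
    stage_specific_module: tuple[int, str, float] | None = None
    area_coupling: tuple[int, float, float, float] | None = (0, 0.8, 150.0, 3000.0)
    noise_sd: float = 1.0
    baseline_log_expr_range: tuple[float, float] = (2.0, 6.0)
    dropout_rate: float = 0.1
    seed: int = 0

    @property
    def stages(self) -> list[str]:
        return list(self.n_cells_per_stage)

    @property
    def n_cells(self) -> int:
        return int(sum(self.n_cells_per_stage.values()))

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not self.n_cells_per_stage or any(
            n <= 0 for n in self.n_cells_per_stage.values()
        ):
            raise ValueError("each stage needs a positive cell count")
        sizes = [m.size for m in self.modules]
        if any(s <= 0 for s in sizes):
            raise ValueError("module sizes must be positive")
        if sum(sizes) > self.n_genes:
            raise ValueError(
                f"module sizes sum to {sum(sizes)} > n_genes = {self.n_genes}"
            )
        if any(m.loading_sd < 0 for m in self.modules) or self.noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.stage_activity is not None:
            sa = np.asarray(self.stage_activity, dtype=float)
            if sa.shape != (len(self.modules), len(self.stages)):
                raise ValueError(
                    "stage_activity must have shape (n_modules, n_stages) = "
                    f"{(len(self.modules), len(self.stages))}, got {sa.shape}"
                )
        if self.stage_specific_module is not None:
            idx, stage, frac = self.stage_specific_module
            if not 0 <= idx < len(self.modules):
                raise ValueError("stage_specific_module index out of range")
            if stage not in self.n_cells_per_stage:
                raise ValueError(f"unknown stage label {stage!r}")
            if not 0.0 < frac <= 1.0:
                raise ValueError("active_fraction must lie in (0, 1]")
        if self.area_coupling is not None:
            idx, _alpha, a_sd, baseline = self.area_coupling
            if not 0 <= idx < max(len(self.modules), 1):
                raise ValueError("area_coupling module index out of range")
            if a_sd < 0:
                raise ValueError("area_noise_sd must be non-negative")
            if baseline <= 0:
                raise ValueError("area_baseline must be positive")


@dataclass
class SimTruth:
    """Ground-truth annotations of a simulated dataset.

    ``gene_module`` maps genes to planted module index (-1 = background);
    ``factor_scores`` are the realized factors (modules x cells);
    ``cell_cluster`` labels each cell by the distinct factor-mean pattern
    it was drawn from (sorted lexicographically, 0-based).
    """

    gene_module: pd.Series
    factor_scores: pd.DataFrame
    cell_stage: pd.Series
    cell_cluster: pd.Series
    area: pd.Series


def default_config(**overrides) -> SimConfig:
    """Study-scale default: 10k genes, 396 cells over 6 stages, 8 planted
    modules, one module active in 30% of week-2 cells, module 0 coupled
    to cell area."""
    modules = [
        ModuleSpec(150), ModuleSpec(120), ModuleSpec(100), ModuleSpec(80),
        ModuleSpec(60), ModuleSpec(60), ModuleSpec(40), ModuleSpec(30),
    ]
    # Rows: per-stage factor means; amplitude 2 against unit factor noise,
    # patterns chosen so each stage has a distinct activity signature.
    stage_activity = np.array(
        [
            #  sham   d3    w1    w2    w4    w8
            [0.0,  2.0,  2.0,  1.0,  0.0, -1.0],   # M0: early activation (area-coupled)
            [0.0,  2.0,  0.0, -1.0, -2.0, -2.0],   # M1: transient early
            [2.0,  0.0, -2.0, -2.0,  0.0,  2.0],   # M2: repressed mid-course
            [0.0,  0.0,  2.0,  2.0,  2.0,  0.0],   # M3: sustained mid
            [-2.0, -2.0,  0.0,  0.0,  2.0,  2.0],  # M4: late activation
            [0.0,  0.0,  0.0,  5.0,  0.0,  0.0],   # M5: burst activation in a subset of w2
            #     (strong ~30-fold induction, as for a stress-response program)
            [1.0, -1.0,  1.0, -1.0,  1.0, -1.0],   # M6: oscillating
            [-1.0,  1.0, -1.0,  1.0, -1.0,  1.0],  # M7: anti-phase to M6
        ]
    )
    cfg = SimConfig(modules=modules, stage_activity=stage_activity,
                    stage_specific_module=(5, "w2", 0.3))
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


def module_recovery_config(seed: int = 1) -> SimConfig:
    """Benchmark condition for module recovery: 2,000 genes, 300 cells
    over 6 stages, five planted modules of 50-150 genes (loading 1.0 +/-
    0.3), stage-patterned factors of amplitude 2, expression noise sd
    1.0."""
    return SimConfig(
        n_genes=2000,
        n_cells_per_stage={s: 50 for s in DEFAULT_STAGES},
        modules=[
            ModuleSpec(150), ModuleSpec(120), ModuleSpec(100),
            ModuleSpec(70), ModuleSpec(50),
        ],
        stage_activity=np.array(
            [
                [0, 2, 2, 1, 0, -1],
                [0, 2, 0, -1, -2, -2],
                [2, 0, -2, -2, 0, 2],
                [0, 0, 2, 2, 2, 0],
                [-2, -2, 0, 0, 2, 2],
            ],
            dtype=float,
        ),
        stage_specific_module=None,
        noise_sd=1.0,
        seed=seed,
    )


def stage_specific_config(seed: int = 0) -> SimConfig:
    """Benchmark condition for stage-specific module discovery: 800
    genes, 240 cells, three globally active modules plus one 80-gene
    module burst-activated (mean 5, ~30-fold) in 30% of week-2 cells
    and silent elsewhere."""
    return SimConfig(
        n_genes=800,
        n_cells_per_stage={s: 40 for s in DEFAULT_STAGES},
        modules=[
            ModuleSpec(100), ModuleSpec(80), ModuleSpec(60), ModuleSpec(80),
        ],
        stage_activity=np.array(
            [
                [0, 2, 2, 1, 0, -1],
                [2, 0, -2, -2, 0, 2],
                [-2, -2, 0, 0, 2, 2],
                [0, 0, 0, 5, 0, 0],
            ],
            dtype=float,
        ),
        stage_specific_module=(3, "w2", 0.3),
        noise_sd=1.0,
        seed=seed,
    )


def seven_cluster_config(seed: int = 1) -> SimConfig:
    """Benchmark condition for the cluster-number sweep: seven cell
    states over 1,200 genes and 480 cells. Six post-overload states
    each carry a strong marker module (amplitude 6); the baseline
    (sham-like) state is larger (120 cells) and looser (amplitude 3),
    mirroring the diffuse baseline population of resting
    cardiomyocytes. The looseness makes the k = 8 cut carve the
    baseline cloud, producing the drastic out-of-bag error increase
    past the true cluster number."""
    stages = ["sham", "d3", "w1", "w2e", "w2l", "w4", "w8"]
    activity = np.zeros((7, 7))
    activity[0, 0] = 3.0
    for j in range(1, 7):
        activity[j, j] = 6.0
    return SimConfig(
        n_genes=1200,
        n_cells_per_stage={s: (120 if s == "sham" else 60) for s in stages},
        modules=[
            ModuleSpec(120), ModuleSpec(100), ModuleSpec(90), ModuleSpec(80),
            ModuleSpec(70), ModuleSpec(60), ModuleSpec(60),
        ],
        stage_activity=activity,
        stage_specific_module=None,
        noise_sd=1.0,
        seed=seed,
    )


def morphology_config(seed: int = 0) -> SimConfig:
    """Benchmark condition for morphology integration: 600 genes, 300
    early-hypertrophy cells, three modules, module 0 coupled to cell
    area with coefficient 0.8 around a 3,000 um^2 baseline."""
    return SimConfig(
        n_genes=600,
        n_cells_per_stage={"w1": 300},
        modules=[ModuleSpec(80), ModuleSpec(60), ModuleSpec(60)],
        stage_activity=np.zeros((3, 1)),
        stage_specific_module=None,
        area_coupling=(0, 0.8, 150.0, 3000.0),
        noise_sd=1.0,
        seed=seed,
    )


def simulate_cells(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Draw one dataset: (expression RPKM-scale genes x cells, metadata, truth).

    Deterministic given ``config.seed``: the same config yields
    bit-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    stages = config.stages
    n_modules = len(config.modules)
    n_genes, n_cells = config.n_genes, config.n_cells
    cell_stage = np.repeat(
        np.arange(len(stages)), [config.n_cells_per_stage[s] for s in stages]
    )
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    cell_ids = [
        f"{stage}_{j:03d}"
        for stage in stages
        for j in range(config.n_cells_per_stage[stage])
    ]

    if config.stage_activity is None:
        activity = np.zeros((n_modules, len(stages)))
    else:
        activity = np.asarray(config.stage_activity, dtype=float)

    # Per-cell factor means; the stage-specific module is silenced outside
    # its active Bernoulli subset so its co-expression signal exists only
    # while those cells are in the dataset.
    means = activity[:, cell_stage] if n_modules else np.zeros((0, n_cells))
    active_scale = np.ones((n_modules, n_cells))
    if config.stage_specific_module is not None:
        m_idx, stage, frac = config.stage_specific_module
        in_stage = cell_stage == stages.index(stage)
        active = rng.random(n_cells) < frac
        on = in_stage & active
        means[m_idx, :] = np.where(on, activity[m_idx, cell_stage], 0.0)
        active_scale[m_idx, :] = np.where(on, 1.0, 0.0)

    factors = means + active_scale * rng.standard_normal((n_modules, n_cells))

    # Loadings: contiguous gene blocks, module m occupying its slice.
    gene_module = np.full(n_genes, -1, dtype=int)
    loadings = np.zeros((n_genes, n_modules))
    offset = 0
    for m, spec in enumerate(config.modules):
        sl = slice(offset, offset + spec.size)
        gene_module[sl] = m
        loadings[sl, m] = rng.normal(spec.loading_mean, spec.loading_sd, spec.size)
        offset += spec.size

    low, high = config.baseline_log_expr_range
    baseline = rng.uniform(low, high, n_genes)
    log_expr = baseline[:, None] + loadings @ factors
    if config.noise_sd > 0:
        log_expr = log_expr + rng.normal(0.0, config.noise_sd, (n_genes, n_cells))

    expr = np.clip(np.exp2(log_expr) - 1.0, 0.0, None)
    if config.dropout_rate > 0:
        expr[rng.random((n_genes, n_cells)) < config.dropout_rate] = 0.0

    # Cell area coupled to one module's factor.
    if config.area_coupling is not None and n_modules:
        m_idx, alpha, a_sd, a0 = config.area_coupling
        area = a0 + alpha * factors[m_idx] * a0 / 10.0
        if a_sd > 0:
            area = area + rng.normal(0.0, a_sd, n_cells)
        area = np.clip(area, 1.0, None)
    else:
        area = np.full(n_cells, np.nan)

    # Cluster truth = distinct realized factor-mean patterns.
    patterns = means.T.round(12)
    uniq = sorted({tuple(row) for row in patterns})
    lookup = {pat: i for i, pat in enumerate(uniq)}
    cell_cluster = np.array([lookup[tuple(row)] for row in patterns])

    matrix = pd.DataFrame(expr, index=gene_ids, columns=cell_ids)
    meta = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "stage": [stages[s] for s in cell_stage],
            "genotype": "WT",
            "area_um2": area,
        }
    ).set_index("cell_id", drop=False)
    truth = SimTruth(
        gene_module=pd.Series(gene_module, index=gene_ids, name="module"),
        factor_scores=pd.DataFrame(
            factors, index=[f"M{m}" for m in range(n_modules)], columns=cell_ids
        ),
        cell_stage=pd.Series(
            [stages[s] for s in cell_stage], index=cell_ids, name="stage"
        ),
        cell_cluster=pd.Series(cell_cluster, index=cell_ids, name="cluster"),
        area=pd.Series(area, index=cell_ids, name="area_um2"),
    )
    return matrix, meta, truth


def write_dataset(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    truth: SimTruth | None,
    out_dir: str | os.PathLike,
) -> dict[str, str]:
    """Write matrix/metadata/truth TSVs to ``out_dir``; returns file map."""
    if not matrix.columns.equals(pd.Index(meta["cell_id"])):
        raise ValueError("matrix cell ids do not match metadata cell ids")
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    files = {
        "matrix": os.path.join(out_dir, "matrix.tsv"),
        "metadata": os.path.join(out_dir, "metadata.tsv"),
    }
    _io.write_matrix(matrix, files["matrix"])
    _io.write_metadata(meta, files["metadata"])
    if truth is not None:
        files["gene_module"] = os.path.join(out_dir, "truth_gene_module.tsv")
        files["factors"] = os.path.join(out_dir, "truth_factors.tsv")
        files["cell_cluster"] = os.path.join(out_dir, "truth_cell_cluster.tsv")
        truth.gene_module.rename_axis("gene_id").to_frame().to_csv(
            files["gene_module"], sep="\t"
        )
        truth.factor_scores.rename_axis("module").to_csv(files["factors"], sep="\t")
        pd.DataFrame(
            {
                "cluster": truth.cell_cluster,
                "stage": truth.cell_stage,
                "area_um2": truth.area,
            }
        ).rename_axis("cell_id").to_csv(files["cell_cluster"], sep="\t")
    return files


def read_dataset(
    in_dir: str | os.PathLike,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth | None]:
    """Read back a dataset written by :func:`write_dataset`."""
    in_dir = os.fspath(in_dir)
    matrix = _io.read_matrix(os.path.join(in_dir, "matrix.tsv"))
    meta = _io.read_metadata(os.path.join(in_dir, "metadata.tsv"))
    truth = None
    gm_path = os.path.join(in_dir, "truth_gene_module.tsv")
    if os.path.exists(gm_path):
        gm = pd.read_csv(gm_path, sep="\t", index_col=0)["module"]
        fac = pd.read_csv(os.path.join(in_dir, "truth_factors.tsv"),
                          sep="\t", index_col=0)
        cc = pd.read_csv(os.path.join(in_dir, "truth_cell_cluster.tsv"),
                         sep="\t", index_col=0, dtype={"cell_id": str})
        truth = SimTruth(
            gene_module=gm,
            factor_scores=fac,
            cell_stage=cc["stage"],
            cell_cluster=cc["cluster"],
            area=cc["area_um2"],
        )
    return matrix, meta, truth
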