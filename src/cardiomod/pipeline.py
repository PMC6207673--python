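"""End-to-end orchestration: QC -> network -> classification ->
stage-specific modules -> morphology, with a single config, one
top-level seed, and a JSON run manifest for reproducibility.

Per-stage seeds are derived from the top-level seed by stable hashing
of the stage name, so partial reruns reproduce each stage's randomness
independently of the others.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import zlib
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import io as _io
from . import morphology as _morph
from .classify import ModuleClassifier
from .network import CoexpressionNetwork, NetworkParams
from .overlap import detect_stage_specific
from .qc import filter_cells, filter_genes

__all__ = ["PipelineConfig", "validate_inputs", "run_all", "stage_seed"]


@dataclass
class PipelineConfig:
    """Structured configuration of one full analysis run."""

    matrix_path: str
    metadata_path: str
    out_dir: str
    seed: int = 0
    # QC
    min_genes: int = 5000
    cell_rpkm_threshold: float = 0.1
    gene_rpkm_threshold: float = 10.0
    gene_min_cells: int = 1
    # network
    network: NetworkParams = field(default_factory=NetworkParams)
    # classification
    k_min: int = 4
    k_max: int = 10
    min_cluster_fraction: float = 0.05
    # stage-specific
    excluded_stage: str | None = None
    stage_threshold_neglogp: float = 10.0
    # morphology
    top_n_genes: int = 300

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        net = NetworkParams(**raw.pop("network", {}))
        return cls(network=net, **raw)

    def validate(self) -> None:
        for path in (self.matrix_path, self.metadata_path):
            if not os.path.exists(path):
                raise FileNotFoundError(path)
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("need 2 <= k_min <= k_max")
        if not 0 < self.min_cluster_fraction < 1:
            raise ValueError("min_cluster_fraction must lie in (0, 1)")


def stage_seed(top_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (zlib.crc32(f"{stage}:{top_seed}".encode()) ^ top_seed) % (2**31 - 1)


def validate_inputs(matrix_path: str, metadata_path: str) -> dict:
    """Parse and cross-check the matrix and metadata files."""
    report = {"ok": True, "errors": []}
    try:
        matrix = _io.read_matrix(matrix_path)
    except Exception as exc:  # report parse failures, don't raise
        return {"ok": False, "errors": [f"matrix unreadable: {exc}"]}
    try:
        meta = _io.read_metadata(metadata_path)
    except Exception as exc:
        return {"ok": False, "errors": [f"metadata unreadable: {exc}"]}
    report["n_genes"], report["n_cells"] = map(int, matrix.shape)
    neg = matrix.lt(0)
    if neg.to_numpy().any():
        g = neg.any(axis=1).idxmax()
        c = neg.loc[g].idxmax()
        report["errors"].append(f"negative value at gene {g}, cell {c}")
    if matrix.index.duplicated().any():
        dups = list(matrix.index[matrix.index.duplicated()][:5])
        report["errors"].append(f"duplicated gene ids: {dups}")
    missing = matrix.columns.difference(meta["cell_id"])
    if len(missing):
        report["errors"].append(
            f"cells missing from metadata: {list(missing)[:5]}"
        )
    report["ok"] = not report["errors"]
    return report


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Execute every analysis stage in order; returns the run manifest.

    Each stage writes its outputs under ``out_dir`` and appends a
    summary to the manifest (``manifest.json``). Any stage failure
    aborts the run, leaving a FAILED marker naming the stage.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    manifest = {
        "seed": config.seed,
        "inputs": {
            "matrix": {"path": config.matrix_path,
                       "sha256": _checksum(config.matrix_path)},
            "metadata": {"path": config.metadata_path,
                         "sha256": _checksum(config.metadata_path)},
        },
        "parameters": {
            "qc": {"min_genes": config.min_genes,
                   "cell_rpkm_threshold": config.cell_rpkm_threshold,
                   "gene_rpkm_threshold": config.gene_rpkm_threshold,
                   "gene_min_cells": config.gene_min_cells},
            "network": dataclasses.asdict(config.network),
            "classify": {"k_min": config.k_min, "k_max": config.k_max,
                         "min_cluster_fraction": config.min_cluster_fraction},
            "stage_specific": {"excluded_stage": config.excluded_stage,
                               "threshold_neglogp": config.stage_threshold_neglogp},
            "morphology": {"top_n_genes": config.top_n_genes},
        },
        "stages": [],
    }
    current = "qc"
    try:
        # ---- QC ----
        report = validate_inputs(config.matrix_path, config.metadata_path)
        if not report["ok"]:
            raise ValueError("; ".join(report["errors"]))
        matrix = _io.read_matrix(config.matrix_path)
        meta = _io.read_metadata(config.metadata_path)
        matrix, qc_report = filter_cells(
            matrix, meta, config.min_genes, config.cell_rpkm_threshold
        )
        genes = filter_genes(
            matrix, config.gene_rpkm_threshold, min_cells=config.gene_min_cells
        )
        matrix = matrix.loc[genes]
        meta = meta.loc[matrix.columns]
        qc_report.detected_genes.rename_axis("cell_id").to_frame().assign(
            passed=qc_report.passed
        ).to_csv(os.path.join(config.out_dir, "qc_cells.tsv"), sep="\t")
        manifest["stages"].append({"name": "qc", **qc_report.summary(),
                                   "n_genes_retained": int(len(genes))})

        # ---- network ----
        current = "network"
        net = CoexpressionNetwork(matrix, config.network).fit()
        net.labels.rename_axis("gene_id").to_frame().to_csv(
            os.path.join(config.out_dir, "gene_modules.tsv"), sep="\t"
        )
        net.eigengenes.rename_axis("module").to_csv(
            os.path.join(config.out_dir, "eigengenes.tsv"), sep="\t"
        )
        net.kme.rename_axis("gene_id").to_csv(
            os.path.join(config.out_dir, "kme.tsv"), sep="\t"
        )
        manifest["stages"].append({
            "name": "network",
            "beta": int(net.params.beta),
            "n_modules": net.n_modules,
            "module_sizes": {k: int(v) for k, v in net.module_sizes.items()},
        })

        # ---- classification ----
        current = "classify"
        clf = ModuleClassifier(
            net.eigengenes.T,
            k_range=range(config.k_min, config.k_max + 1),
            seed=stage_seed(config.seed, "classify"),
            min_cluster_fraction=config.min_cluster_fraction,
        ).fit()
        clf.labels.rename_axis("cell_id").to_frame().to_csv(
            os.path.join(config.out_dir, "cell_clusters.tsv"), sep="\t"
        )
        with open(os.path.join(config.out_dir, "classifier.json"), "w") as fh:
            json.dump(clf.to_dict(), fh, indent=1)
        manifest["stages"].append({
            "name": "classify",
            "chosen_k": clf.chosen_k,
            "selected_modules": list(clf.selected_modules),
            "oob_error": {int(k): float(v) for k, v in clf.error_rates.items()},
        })

        # ---- stage-specific modules ----
        current = "stage_specific"
        if config.excluded_stage is not None:
            flagged, ov, _, _ = detect_stage_specific(
                matrix, meta, config.excluded_stage, config.network,
                config.stage_threshold_neglogp,
            )
            ov.table.to_csv(
                os.path.join(config.out_dir, "module_overlap.tsv"),
                sep="\t", index=False,
            )
            manifest["stages"].append({
                "name": "stage_specific",
                "excluded_stage": config.excluded_stage,
                "threshold_neglogp": config.stage_threshold_neglogp,
                "flagged_modules": [str(m) for m in flagged],
            })
        else:
            manifest["stages"].append({"name": "stage_specific",
                                       "skipped": "no excluded_stage configured"})

        # ---- morphology ----
        current = "morphology"
        if "area_um2" in meta.columns and meta["area_um2"].notna().all():
            rep = _morph.morphology_report(
                matrix, meta["area_um2"], eigengenes=net.eigengenes,
                top_n=config.top_n_genes,
            )
            rep["module_area_correlation"].rename_axis("module").to_csv(
                os.path.join(config.out_dir, "module_area_correlation.tsv"),
                sep="\t",
            )
            rep["gene_area_correlation"].rename_axis("gene_id").to_csv(
                os.path.join(config.out_dir, "gene_area_correlation.tsv"),
                sep="\t",
            )
            top_module = rep["module_area_correlation"].index[0]
            manifest["stages"].append({
                "name": "morphology",
                "top_area_module": str(top_module),
                "pc1_area_r": float(
                    rep["pc_area_correlation"].loc["PC1", "r"]
                ),
            })
        else:
            manifest["stages"].append({"name": "morphology",
                                       "skipped": "no per-cell area in metadata"})
    except Exception as exc:
        manifest["failed_stage"] = current
        manifest["error"] = str(exc)
        with open(os.path.join(config.out_dir, "FAILED"), "w") as fh:
            fh.write(f"{current}: {exc}\n")
        with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1)
        raise RuntimeError(f"pipeline failed at stage {current!r}: {exc}") from exc

    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
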