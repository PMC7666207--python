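"""End-to-end processing chain and its configuration.

``cluster_pipeline`` strings together QC, log-normalisation, HVG
selection, covariate regression + scaling, PCA, SNN graph construction,
Louvain clustering, merging of near-identical clusters and exclusion of
non-CD4 clusters — the exact chain both the reference and every
subsampled dataset pass through in the benchmark. All parameter defaults
are the workflow's standard values (scale factor 10,000, HVG cutoffs
0.0125/8/0.5, clip 10, 20 PCs, k=30 SNN with Jaccard prune 1/15,
resolution 1).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import cluster as cl
from . import embed
from .containers import CountMatrix
from .qc import QCThresholds, apply_qc, compute_qc_metrics, default_mito_genes

__all__ = ["PipelineConfig", "ProcessedSample", "cluster_pipeline"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable parameters of the per-sample processing chain."""

    qc: QCThresholds = field(default_factory=QCThresholds)
    scale_factor: float = 10_000.0
    hvg_mean_low: float = 0.0125
    hvg_mean_high: float = 8.0
    hvg_disp_low: float = 0.5
    hvg_n_bins: int = 20
    scale_clip: float = 10.0
    n_pcs: int = 20
    snn_k: int = 30
    snn_prune: float = 1 / 15
    resolution: float = 1.0
    cluster_method: str = "louvain"
    merge_max_de_genes: int = 10
    exclude_min_expressing_frac: float = 0.25
    required_markers: tuple = cl.DEFAULT_REQUIRED_MARKERS
    rf_n_trees: int = 500
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["qc"] = asdict(self.qc)
        d["required_markers"] = list(self.required_markers)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "qc" in d and isinstance(d["qc"], dict):
            d["qc"] = QCThresholds(**d["qc"])
        if "required_markers" in d:
            d["required_markers"] = tuple(d["required_markers"])
        return cls(**d)


@dataclass
class ProcessedSample:
    """Everything the benchmark needs from one processed dataset."""

    cm_qc: CountMatrix
    qc_report: pd.DataFrame
    norm: embed.NormalizedMatrix
    hvgs: list
    hvg_stats: pd.DataFrame
    pca: embed.PCAResult
    labels_raw: cl.ClusterLabels
    labels: cl.ClusterLabels          # post merge + exclusion
    exclusion_report: pd.DataFrame


def cluster_pipeline(
    cm: CountMatrix,
    cfg: PipelineConfig = PipelineConfig(),
    seed: int | None = None,
    skip_qc: bool = False,
) -> ProcessedSample:
    """QC -> normalise -> HVG -> scale/regress -> PCA -> SNN -> Louvain
    -> merge -> exclude non-target clusters.

    ``skip_qc`` is for inputs that already passed the identical QC (e.g.
    cell subsets drawn from a QC'd reference and re-QC'd during
    subsampling)."""
    if seed is None:
        seed = cfg.seed
    mito = default_mito_genes(cm)
    if skip_qc:
        cm_qc, qc_report = cm, pd.DataFrame(
            {"step": [], "n_removed": [], "n_remaining": [], "axis": []}
        )
    else:
        cm_qc, qc_report = apply_qc(cm, cfg.qc, mito)

    norm = embed.log_normalize(cm_qc, cfg.scale_factor)
    hvgs, hvg_stats = embed.find_variable_genes(
        norm, cfg.hvg_mean_low, cfg.hvg_mean_high, cfg.hvg_disp_low, cfg.hvg_n_bins
    )
    min_hvgs = cfg.n_pcs + 1
    if len(hvgs) < min_hvgs:
        fallback = (
            hvg_stats[np.isfinite(hvg_stats["scaled_dispersion"])]
            .sort_values("scaled_dispersion", ascending=False)
            .head(max(min_hvgs, 100))
            .index.tolist()
        )
        log.warning(
            "only %d HVGs passed cutoffs; falling back to top %d by scaled dispersion",
            len(hvgs), len(fallback),
        )
        hvgs = fallback

    metrics = compute_qc_metrics(cm_qc, [g for g in mito if g in set(cm_qc.gene_symbols)])
    covariates = metrics[["n_umi", "pct_mito"]]
    scaled, scaled_genes = embed.scale_and_regress(
        norm, covariates, genes=hvgs, clip=cfg.scale_clip
    )
    n_pcs = min(cfg.n_pcs, min(scaled.shape) - 1)
    pca = embed.run_pca(scaled, scaled_genes, n_pcs=n_pcs, seed=seed)

    k = min(cfg.snn_k, cm_qc.n_cells - 1)
    graph = cl.build_snn_graph(pca.embeddings, k=k, prune=cfg.snn_prune)
    labels_raw = cl.louvain_cluster(
        graph, resolution=cfg.resolution, seed=seed, barcodes=cm_qc.barcodes,
        method=cfg.cluster_method,
    )
    merged = cl.merge_similar_clusters(
        labels_raw, norm, max_de_genes=cfg.merge_max_de_genes
    )
    present_markers = [m for m in cfg.required_markers if m in set(cm_qc.gene_symbols)]
    if present_markers:
        labels, exclusion_report = cl.exclude_nontarget_clusters(
            merged, cm_qc,
            required_markers=present_markers,
            min_expressing_frac=cfg.exclude_min_expressing_frac,
        )
    else:
        log.warning("no lineage markers on gene axis; skipping non-target exclusion")
        labels = cl.ClusterLabels(merged.labels, merged.barcodes, "filtered")
        exclusion_report = pd.DataFrame(columns=["cluster", "excluded"])
    return ProcessedSample(
        cm_qc=cm_qc,
        qc_report=qc_report,
        norm=norm,
        hvgs=hvgs,
        hvg_stats=hvg_stats,
        pca=pca,
        labels_raw=labels_raw,
        labels=labels,
        exclusion_report=exclusion_report,
    )
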