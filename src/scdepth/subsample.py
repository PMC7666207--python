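"""Read-depth thinning, cell-number subsampling and sequencing metrics.

Read subsampling acts on the read-multiplicity model: conceptually every
read is kept i.i.d. Bernoulli(f); a UMI survives when at least one of its
reads survives. Per-entry read totals are split over that entry's UMIs
(each UMI holds one read plus a multinomial share of the extras) so the
thinning can be carried out without per-read records. Cell subsampling
draws a uniform barcode subset and re-applies QC, mirroring the benchmark
design in which every subsampled dataset is quality-controlled afresh.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix, ReadMultiplicities
from .qc import QCThresholds, apply_qc

__all__ = [
    "DepthGrid",
    "CellGrid",
    "DepthMetrics",
    "subsample_reads",
    "fraction_for_target_depth",
    "compute_depth_metrics",
    "subsample_cells",
]


def _default_depths() -> tuple:
    return tuple(range(20_000, 100_001, 10_000))


def _default_cells() -> tuple:
    return tuple(range(500, 4001, 500))


@dataclass(frozen=True)
class DepthGrid:
    """Target mean reads/cell values with replication."""

    targets: tuple = field(default_factory=_default_depths)
    n_replicates: int = 3
    base_seed: int = 0

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.targets):
            raise ValueError("depth targets must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def replicate_seed(self, target, replicate: int) -> int:
        return int(self.base_seed + 1000 * int(target) % 2**20 + replicate)


@dataclass(frozen=True)
class CellGrid:
    """Target cell counts with replication."""

    targets: tuple = field(default_factory=_default_cells)
    n_replicates: int = 3
    base_seed: int = 0

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.targets):
            raise ValueError("cell targets must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class DepthMetrics:
    """Sequencing metrics of one dataset at one depth."""

    mean_reads_per_cell: float
    sequencing_saturation: float
    total_genes_detected: int
    median_genes_per_cell: float
    median_umi_per_cell: float

    def as_dict(self) -> dict:
        return {
            "mean_reads_per_cell": self.mean_reads_per_cell,
            "sequencing_saturation": self.sequencing_saturation,
            "total_genes_detected": self.total_genes_detected,
            "median_genes_per_cell": self.median_genes_per_cell,
            "median_umi_per_cell": self.median_umi_per_cell,
        }


def subsample_reads(
    cm: CountMatrix,
    reads: ReadMultiplicities,
    fraction: float,
    seed: int = 0,
) -> tuple[CountMatrix, ReadMultiplicities]:
    """Thin reads by keeping each read with probability ``fraction``.

    Entry totals are distributed over the entry's UMIs (1 read each plus a
    multinomial split of the extras), each UMI's reads are thinned
    binomially, and a UMI is retained iff at least one read survives.
    Thinned counts are elementwise <= the originals; deterministic given
    ``seed``. When every UMI carries exactly one read this reduces to
    binomial thinning of the counts.
    """
    if not 0 <= fraction <= 1:
        raise ValueError(f"fraction must be in [0,1], got {fraction}")
    reads.validate_against(cm)
    if fraction == 1.0:
        return cm.copy(), ReadMultiplicities(reads.reads.copy())
    # counts and reads share sparsity (validated) and are canonical csr,
    # so their coo data arrays align entry-for-entry
    coo = cm.counts.tocoo()
    k = coo.data.astype(np.int64)
    r_tot = reads.reads.tocoo().data.astype(np.int64)
    rng = np.random.default_rng(seed)
    if fraction == 0.0:
        empty = sp.csr_matrix(cm.counts.shape, dtype=np.int64)
        out = CountMatrix(empty, cm.gene_symbols.copy(), cm.barcodes.copy(), cm.cell_meta.copy())
        return out, ReadMultiplicities(empty.copy())

    remaining_extra = r_tot - k
    surv_counts = np.zeros_like(k)
    surv_reads = np.zeros_like(k)
    max_k = int(k.max()) if k.size else 0
    active = np.arange(k.size)
    for m in range(1, max_k + 1):
        active = active[k[active] >= m]
        if active.size == 0:
            break
        slots_left = k[active] - m + 1
        extra_m = rng.binomial(remaining_extra[active], 1.0 / slots_left)
        remaining_extra[active] -= extra_m
        umi_reads = 1 + extra_m
        kept = rng.binomial(umi_reads, fraction)
        surv_reads[active] += kept
        surv_counts[active] += (kept > 0).astype(np.int64)

    keep = surv_counts > 0
    shape = cm.counts.shape
    thin_counts = sp.csr_matrix(
        (surv_counts[keep], (coo.row[keep], coo.col[keep])), shape=shape
    )
    thin_reads = sp.csr_matrix(
        (surv_reads[keep], (coo.row[keep], coo.col[keep])), shape=shape
    )
    out = CountMatrix(
        thin_counts, cm.gene_symbols.copy(), cm.barcodes.copy(), cm.cell_meta.copy()
    )
    return out, ReadMultiplicities(thin_reads)


def fraction_for_target_depth(
    reads: ReadMultiplicities, target_mean_reads_per_cell: float
) -> float:
    """Thinning fraction achieving a target mean reads/cell."""
    n_cells = reads.reads.shape[1]
    realized = reads.total_reads / n_cells
    if target_mean_reads_per_cell > realized:
        raise ValueError(
            f"target {target_mean_reads_per_cell} exceeds realized depth {realized:.1f}"
        )
    return float(target_mean_reads_per_cell / realized)


def compute_depth_metrics(cm: CountMatrix, reads: ReadMultiplicities) -> DepthMetrics:
    """Saturation and per-cell gene/UMI summaries for one dataset."""
    reads.validate_against(cm)
    total_umis = int(cm.counts.sum())
    total_reads = reads.total_reads
    if total_reads == 0:
        warnings.warn("zero total reads; saturation defined as 0")
        saturation = 0.0
    else:
        saturation = 1.0 - total_umis / total_reads
    genes_per_cell = cm.counts.getnnz(axis=0)
    umis_per_cell = np.asarray(cm.counts.sum(axis=0)).ravel()
    return DepthMetrics(
        mean_reads_per_cell=total_reads / cm.n_cells if cm.n_cells else 0.0,
        sequencing_saturation=saturation,
        total_genes_detected=int((cm.counts.getnnz(axis=1) > 0).sum()),
        median_genes_per_cell=float(np.median(genes_per_cell)) if cm.n_cells else 0.0,
        median_umi_per_cell=float(np.median(umis_per_cell)) if cm.n_cells else 0.0,
    )


def subsample_cells(
    cm: CountMatrix,
    n: int,
    seed: int = 0,
    thresholds: QCThresholds = QCThresholds(),
    mito_genes=None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Uniform random subset of ``n`` cells followed by a fresh QC pass.

    The output may hold fewer than ``n`` cells because QC re-runs on the
    subset. Deterministic given ``seed``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n > cm.n_cells:
        raise ValueError(f"requested {n} cells but only {cm.n_cells} available")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(cm.n_cells, size=n, replace=False))
    subset = cm.subset_cells(idx)
    return apply_qc(subset, thresholds, mito_genes)
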