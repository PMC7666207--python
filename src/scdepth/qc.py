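"""Cell and gene quality control.

Filtering follows the droplet-QC convention of a hard minimum filter
(cells expressing < 200 genes, genes expressed in < 3 cells) followed by
removal of outlier cells lying outside three median absolute deviations
(MADs) of mitochondrial percentage (high side), detected genes and total
UMIs (both sides).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountMatrix, ReadMultiplicities

__all__ = [
    "QCThresholds",
    "EmptyDatasetError",
    "compute_qc_metrics",
    "mad_outlier_flags",
    "apply_qc",
    "default_mito_genes",
]

#: normal-consistency constant relating MAD to the standard deviation
MAD_SCALE = 1.4826


class EmptyDatasetError(RuntimeError):
    """Raised when QC would remove every cell."""


@dataclass(frozen=True)
class QCThresholds:
    min_genes_per_cell: int = 200
    min_cells_per_gene: int = 3
    n_mads: float = 3.0

    def __post_init__(self) -> None:
        if self.min_genes_per_cell < 0 or self.min_cells_per_gene < 0 or self.n_mads < 0:
            raise ValueError("QC thresholds must be non-negative")


def default_mito_genes(cm: CountMatrix) -> list[str]:
    """Genes with the conventional mitochondrial ``MT-`` symbol prefix."""
    return [s for s in cm.gene_symbols if s.startswith("MT-")]


def compute_qc_metrics(cm: CountMatrix, mito_genes=None) -> pd.DataFrame:
    """Per-cell QC metrics: detected genes, total UMIs, % mitochondrial.

    Cells with zero total counts get ``pct_mito = 0`` (they are removed by
    the minimum-genes filter anyway).
    """
    if mito_genes is None:
        mito_genes = default_mito_genes(cm)
    missing = set(mito_genes) - set(cm.gene_symbols)
    if missing:
        raise KeyError(f"mito genes absent from gene axis: {sorted(missing)}")
    counts = cm.counts.tocsc()
    n_umi = np.asarray(counts.sum(axis=0)).ravel()
    n_genes = counts.getnnz(axis=0)
    if mito_genes:
        mito_counts = np.asarray(
            counts[cm.gene_index(mito_genes), :].sum(axis=0)
        ).ravel()
    else:
        mito_counts = np.zeros_like(n_umi, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(n_umi > 0, 100.0 * mito_counts / np.maximum(n_umi, 1), 0.0)
    return pd.DataFrame(
        {
            "n_genes_detected": n_genes.astype(int),
            "n_umi": n_umi.astype(int),
            "pct_mito": pct,
        },
        index=pd.Index(cm.barcodes, name="barcode"),
    )


def mad_outlier_flags(values, n_mads: float = 3.0, side: str = "both") -> np.ndarray:
    """Flag values outside ``n_mads`` scaled MADs of the median.

    The MAD is scaled by 1.4826 (normal consistency). With a zero MAD any
    value different from the median is flagged (hence none when all values
    are equal). ``side`` selects two-sided flagging or high-side only.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("mad_outlier_flags: empty input")
    if not np.all(np.isfinite(values)):
        raise ValueError("mad_outlier_flags: non-finite values")
    if side not in ("both", "upper"):
        raise ValueError(f"unknown side: {side!r}")
    if not math.isfinite(n_mads):
        return np.zeros(values.shape, dtype=bool)
    med = np.median(values)
    mad = MAD_SCALE * np.median(np.abs(values - med))
    dev = values - med
    if side == "upper":
        return dev > n_mads * mad
    return np.abs(dev) > n_mads * mad


def apply_qc(
    cm: CountMatrix,
    thresholds: QCThresholds = QCThresholds(),
    mito_genes=None,
    reads: ReadMultiplicities | None = None,
):
    """Run the full QC cascade and return the filtered matrix plus report.

    Steps, in order: (1) drop cells with fewer detected genes than
    ``min_genes_per_cell``; (2) drop genes expressed in fewer than
    ``min_cells_per_gene`` cells; (3) recompute metrics; (4) drop cells
    flagged as MAD outliers on pct_mito (high), n_genes (both sides) or
    n_umi (both sides), as a union of flags.

    Returns ``(filtered, report)`` or ``(filtered, report, filtered_reads)``
    when ``reads`` is given. ``report`` is a step/n_removed/n_remaining
    table serialisable as TSV.
    """
    if mito_genes is None:
        mito_genes = default_mito_genes(cm)
    steps = []

    metrics = compute_qc_metrics(cm, mito_genes)
    keep_cells = (metrics["n_genes_detected"] >= thresholds.min_genes_per_cell).to_numpy()
    steps.append(("min_genes_per_cell", int((~keep_cells).sum())))
    out = cm.subset_cells(keep_cells)
    if reads is not None:
        reads = reads.subset_cells(keep_cells)
    if out.n_cells == 0:
        raise EmptyDatasetError("all cells removed by the minimum-genes filter")

    cells_per_gene = out.counts.getnnz(axis=1)
    keep_genes = cells_per_gene >= thresholds.min_cells_per_gene
    steps.append(("min_cells_per_gene", int((~keep_genes).sum())))
    mito_kept = [g for g in mito_genes if g in set(out.gene_symbols[keep_genes])]
    out = out.subset_genes(keep_genes)
    if reads is not None:
        reads = reads.subset_genes(keep_genes)

    metrics = compute_qc_metrics(out, mito_kept)
    flags = (
        mad_outlier_flags(metrics["pct_mito"], thresholds.n_mads, side="upper")
        | mad_outlier_flags(metrics["n_genes_detected"], thresholds.n_mads)
        | mad_outlier_flags(metrics["n_umi"], thresholds.n_mads)
        | (metrics["n_umi"] == 0).to_numpy()
    )
    steps.append(("mad_outliers", int(flags.sum())))
    out = out.subset_cells(~flags)
    if reads is not None:
        reads = reads.subset_cells(~flags)
    if out.n_cells == 0:
        raise EmptyDatasetError("all cells removed by MAD outlier filtering")

    report = pd.DataFrame(
        {
            "step": [s for s, _ in steps],
            "n_removed": [n for _, n in steps],
            "n_remaining": [
                cm.n_cells - steps[0][1],
                cm.n_genes - steps[1][1],
                out.n_cells,
            ],
            "axis": ["cells", "genes", "cells"],
        }
    )
    if reads is not None:
        return out, report, reads
    return out, report
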