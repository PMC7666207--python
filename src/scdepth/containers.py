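"""Core in-memory containers for droplet scRNA-seq count data.

The package works on genes x cells sparse UMI count matrices (the 10x
orientation) with an optional parallel matrix of per-entry read totals,
which is what makes read-level downsampling expressible on counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["CountMatrix", "ReadMultiplicities", "TruthLabels"]


def _as_csr_int(m) -> sp.csr_matrix:
    m = sp.csr_matrix(m)
    if m.nnz and not np.issubdtype(m.dtype, np.integer):
        data = m.data
        if not np.allclose(data, np.round(data)):
            raise ValueError("count matrix entries must be integers")
        m = m.astype(np.int64)
    else:
        m = m.astype(np.int64)
    if m.nnz and m.data.min() < 0:
        raise ValueError("count matrix entries must be non-negative")
    m.eliminate_zeros()
    m.sort_indices()
    return m


@dataclass
class CountMatrix:
    """Sparse genes x cells UMI count matrix with named axes.

    Attributes
    ----------
    counts
        ``scipy.sparse.csr_matrix`` of non-negative integers, genes on rows.
    gene_symbols
        Unique gene symbols, one per row (mitochondrial genes carry the
        ``MT-`` prefix).
    barcodes
        Unique cell barcodes, one per column.
    cell_meta
        Per-cell metadata table indexed by barcode (e.g. condition).
    """

    counts: sp.csr_matrix
    gene_symbols: np.ndarray
    barcodes: np.ndarray
    cell_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.counts = _as_csr_int(self.counts)
        self.gene_symbols = np.asarray(self.gene_symbols, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if self.counts.shape != (len(self.gene_symbols), len(self.barcodes)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_symbols)} genes x {len(self.barcodes)} cells"
            )
        if len(set(self.gene_symbols)) != len(self.gene_symbols):
            raise ValueError("duplicate gene symbols")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("duplicate barcodes")
        if self.cell_meta.empty:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.barcodes, name="barcode"))
        else:
            self.cell_meta = self.cell_meta.loc[list(self.barcodes)]
            self.cell_meta.index.name = "barcode"

    # -- basic geometry ---------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, symbols) -> np.ndarray:
        """Row indices of ``symbols``; raises KeyError on a missing symbol."""
        lookup = {s: i for i, s in enumerate(self.gene_symbols)}
        try:
            return np.array([lookup[s] for s in symbols], dtype=int)
        except KeyError as exc:  # pragma: no cover - message detail
            raise KeyError(f"gene symbol not present: {exc.args[0]}") from None

    # -- subsetting -------------------------------------------------------
    def subset_cells(self, idx) -> "CountMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            counts=self.counts[:, idx],
            gene_symbols=self.gene_symbols,
            barcodes=self.barcodes[idx],
            cell_meta=self.cell_meta.iloc[idx],
        )

    def subset_genes(self, idx) -> "CountMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            counts=self.counts[idx, :],
            gene_symbols=self.gene_symbols[idx],
            barcodes=self.barcodes,
            cell_meta=self.cell_meta,
        )

    def copy(self) -> "CountMatrix":
        return CountMatrix(
            self.counts.copy(),
            self.gene_symbols.copy(),
            self.barcodes.copy(),
            self.cell_meta.copy(),
        )


@dataclass
class ReadMultiplicities:
    """Per-entry read totals congruent to a :class:`CountMatrix`.

    ``reads[g, c]`` is the total number of sequenced reads supporting the
    UMIs of gene ``g`` in cell ``c``; every UMI carries at least one read.
    """

    reads: sp.csr_matrix

    def __post_init__(self) -> None:
        self.reads = _as_csr_int(self.reads)

    def validate_against(self, cm: CountMatrix) -> None:
        if self.reads.shape != cm.counts.shape:
            raise ValueError("reads matrix shape differs from counts")
        diff = (self.reads - cm.counts).tocoo()
        if diff.data.size and diff.data.min() < 0:
            raise ValueError("reads < counts for some entry (a UMI with no read)")
        # support sets must coincide: zero counts imply zero reads
        support = cm.counts.copy()
        support.data = np.ones_like(support.data)
        rsupport = self.reads.copy()
        rsupport.data = np.ones_like(rsupport.data)
        if (rsupport - support).nnz:
            raise ValueError("reads present where counts are zero (or vice versa)")

    def subset_cells(self, idx) -> "ReadMultiplicities":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return ReadMultiplicities(self.reads[:, idx])

    def subset_genes(self, idx) -> "ReadMultiplicities":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return ReadMultiplicities(self.reads[idx, :])

    @property
    def total_reads(self) -> int:
        return int(self.reads.sum())


@dataclass
class TruthLabels:
    """Ground-truth annotation emitted by the generator.

    ``cells`` is indexed by barcode with columns ``subtype`` and
    ``condition``; ``marker_of`` maps marker gene symbol -> subtype name.
    ``stim_up``/``stim_down`` list the genes boosted/suppressed under
    stimulation.
    """

    cells: pd.DataFrame
    marker_of: dict
    stim_up: list = field(default_factory=list)
    stim_down: list = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = {"subtype", "condition"} - set(self.cells.columns)
        if missing:
            raise ValueError(f"truth table missing columns: {sorted(missing)}")
        self.cells.index.name = "barcode"

    def subtypes(self) -> pd.Series:
        return self.cells["subtype"]
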