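"""10x-style Matrix Market I/O and plain-TSV tables.

A dataset directory holds ``matrix.mtx`` (integer coordinate Matrix
Market, genes x cells), ``barcodes.tsv`` (one barcode per line) and
``features.tsv`` (gene_id TAB gene_symbol). Read multiplicities, when
present, live in ``reads.mtx`` with the same sparsity structure.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CountMatrix, ReadMultiplicities, TruthLabels

__all__ = ["write_10x", "read_10x", "write_truth", "read_truth"]

MATRIX_FILE = "matrix.mtx"
BARCODES_FILE = "barcodes.tsv"
FEATURES_FILE = "features.tsv"
READS_FILE = "reads.mtx"
TRUTH_FILE = "truth.tsv"


def write_10x(cm: CountMatrix, directory, reads: ReadMultiplicities | None = None) -> None:
    """Write a CountMatrix (and optional read totals) in 10x layout."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        str(directory / MATRIX_FILE), cm.counts.tocoo(), field="integer"
    )
    with open(directory / BARCODES_FILE, "w") as fh:
        fh.writelines(f"{b}\n" for b in cm.barcodes)
    with open(directory / FEATURES_FILE, "w") as fh:
        for i, symbol in enumerate(cm.gene_symbols):
            fh.write(f"GSYN{i:05d}\t{symbol}\n")
    if reads is not None:
        reads.validate_against(cm)
        scipy.io.mmwrite(str(directory / READS_FILE), reads.reads.tocoo(), field="integer")


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"missing 10x file: {path}")
    return path


def read_10x(directory) -> CountMatrix:
    """Read a 10x-layout directory back into a CountMatrix."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"not a directory: {directory}")
    try:
        mat = scipy.io.mmread(_require(directory / MATRIX_FILE))
    except ValueError as exc:
        raise ValueError(f"ill-formed Matrix Market file {directory / MATRIX_FILE}: {exc}")
    if not np.issubdtype(np.asarray(mat.data if sp.issparse(mat) else mat).dtype, np.integer):
        data = mat.data if sp.issparse(mat) else np.asarray(mat)
        if not np.allclose(data, np.round(data)):
            raise ValueError(f"non-integer values in {directory / MATRIX_FILE}")
    barcodes = _read_lines(_require(directory / BARCODES_FILE))
    features = pd.read_csv(
        _require(directory / FEATURES_FILE), sep="\t", header=None, dtype=str
    )
    if features.shape[1] < 2:
        raise ValueError(f"ill-formed features file {directory / FEATURES_FILE}: need id and symbol columns")
    return CountMatrix(
        counts=sp.csr_matrix(mat),
        gene_symbols=features.iloc[:, 1].to_numpy(dtype=object),
        barcodes=np.array(barcodes, dtype=object),
    )


def read_reads(directory, cm: CountMatrix) -> ReadMultiplicities:
    directory = Path(directory)
    reads = ReadMultiplicities(sp.csr_matrix(scipy.io.mmread(_require(directory / READS_FILE))))
    reads.validate_against(cm)
    return reads


def _read_lines(path: Path) -> list[str]:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    return [ln for ln in lines if ln]


def write_truth(truth: TruthLabels, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    truth.cells.to_csv(directory / TRUTH_FILE, sep="\t")


def read_truth(directory) -> TruthLabels:
    path = _require(Path(directory) / TRUTH_FILE)
    cells = pd.read_csv(path, sep="\t", index_col="barcode")
    return TruthLabels(cells=cells, marker_of={})
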