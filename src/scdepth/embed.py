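"""Normalisation, variable-gene selection, scaling and PCA.

The processing chain mirrors the classic log-normalise / mean-dispersion
HVG / regress-and-scale / PCA workflow: counts are scaled to a fixed total
per cell and log-transformed; highly variable genes are picked by
z-scoring the log dispersion of back-transformed expression within
equal-frequency mean bins; expression is then regressed on per-cell
covariates (total UMIs, mitochondrial percentage), standardised, clipped,
and reduced to the top principal components.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA

from .containers import CountMatrix

__all__ = [
    "NormalizedMatrix",
    "PCAResult",
    "log_normalize",
    "find_variable_genes",
    "scale_and_regress",
    "run_pca",
]

log = logging.getLogger(__name__)


@dataclass
class NormalizedMatrix:
    """Log-normalised expression, genes x cells, plus named axes."""

    matrix: sp.csr_matrix
    gene_symbols: np.ndarray
    barcodes: np.ndarray
    scale_factor: float = 10_000.0

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]

    def gene_index(self, symbols) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.gene_symbols)}
        return np.array([lookup[s] for s in symbols], dtype=int)

    def dense(self, genes=None) -> np.ndarray:
        if genes is None:
            return np.asarray(self.matrix.todense())
        return np.asarray(self.matrix[self.gene_index(genes), :].todense())


@dataclass
class PCAResult:
    embeddings: np.ndarray          # cells x n_pcs
    loadings: np.ndarray            # genes x n_pcs, orthonormal columns
    variance_explained: np.ndarray  # per component
    gene_symbols: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))


def log_normalize(cm: CountMatrix, scale_factor: float = 10_000.0) -> NormalizedMatrix:
    """``ln(1 + count * scale_factor / cell_total)`` per entry.

    Cells with zero totals are rejected: run QC first.
    """
    totals = np.asarray(cm.counts.sum(axis=0)).ravel()
    if (totals == 0).any():
        raise ValueError(
            "log_normalize: cells with zero total counts present; apply QC first"
        )
    coo = cm.counts.tocoo()
    data = np.log1p(coo.data * (scale_factor / totals[coo.col]))
    mat = sp.csr_matrix((data, (coo.row, coo.col)), shape=cm.counts.shape)
    return NormalizedMatrix(mat, cm.gene_symbols.copy(), cm.barcodes.copy(), scale_factor)


def find_variable_genes(
    norm: NormalizedMatrix,
    mean_low: float = 0.0125,
    mean_high: float = 8.0,
    disp_low: float = 0.5,
    n_bins: int = 20,
) -> tuple[list[str], pd.DataFrame]:
    """Mean/dispersion HVG selection on back-transformed expression.

    Per gene, ``mean = ln(mean(exp(x) - 1) + 1)`` and ``dispersion =
    ln(variance / mean)`` of the back-transformed values; dispersions are
    z-scored within ``n_bins`` equal-frequency bins of the mean. A gene is
    selected when ``mean_low < mean < mean_high`` and its scaled
    dispersion exceeds ``disp_low``. Zero-variance genes are never
    selected. Returns the selected symbols (ordered by decreasing scaled
    dispersion) and the full per-gene statistics table.
    """
    if norm.n_cells < 2:
        raise ValueError("find_variable_genes needs at least 2 cells")
    x = norm.matrix.copy()
    x.data = np.expm1(x.data)
    n = norm.n_cells
    s1 = np.asarray(x.sum(axis=1)).ravel()
    s2 = np.asarray(x.multiply(x).sum(axis=1)).ravel()
    mean_bt = s1 / n
    var_bt = (s2 - n * mean_bt**2) / (n - 1)
    var_bt = np.maximum(var_bt, 0.0)
    # guard against catastrophic cancellation declaring a constant gene variable
    var_bt[var_bt <= 1e-12 * np.maximum(mean_bt**2, 1e-300)] = 0.0
    mean = np.log1p(mean_bt)
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(
            (var_bt > 0) & (mean_bt > 0), np.log(np.maximum(var_bt, 1e-300) / np.maximum(mean_bt, 1e-300)), -np.inf
        )

    stats = pd.DataFrame(
        {"mean": mean, "dispersion": dispersion},
        index=pd.Index(norm.gene_symbols, name="gene"),
    )
    finite = np.isfinite(dispersion)
    scaled = np.full(len(mean), -np.inf)
    if finite.sum() >= 2:
        bins = pd.qcut(mean[finite], q=min(n_bins, finite.sum()), duplicates="drop")
        disp_f = pd.Series(dispersion[finite])
        grouped = disp_f.groupby(bins.codes)
        mu = grouped.transform("mean")
        sd = grouped.transform(lambda s: s.std(ddof=1))
        z = (disp_f - mu) / sd.replace(0.0, np.nan)
        scaled[finite] = z.fillna(0.0).to_numpy()
    stats["scaled_dispersion"] = scaled

    selected = stats[
        (stats["mean"] > mean_low)
        & (stats["mean"] < mean_high)
        & (stats["scaled_dispersion"] > disp_low)
    ]
    ordered = selected.sort_values("scaled_dispersion", ascending=False).index.tolist()
    return ordered, stats


def scale_and_regress(
    norm: NormalizedMatrix,
    covariates: pd.DataFrame,
    genes=None,
    clip: float = 10.0,
) -> tuple[np.ndarray, list[str]]:
    """Regress out covariates per gene, then centre, scale and clip.

    ``covariates`` is a per-cell table (e.g. ``n_umi`` and ``pct_mito``
    columns, raw scale) aligned to the matrix columns. Per gene an OLS fit
    with intercept is computed; residuals are centred, divided by their
    standard deviation and clipped to ``[-clip, clip]``. Collinear
    covariates are dropped (later column wins removal) with a warning.
    Returns ``(scaled genes x cells array, gene_symbols list)``.
    """
    if genes is None:
        genes = list(norm.gene_symbols)
    if len(covariates) != norm.n_cells:
        raise ValueError("covariates must have one row per cell")
    cov = covariates.to_numpy(dtype=float)
    X = np.column_stack([np.ones(norm.n_cells), cov])
    # drop collinear columns, keeping the earliest independent set
    keep = [0]
    for j in range(1, X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
        else:
            name = covariates.columns[j - 1]
            warnings.warn(f"dropping collinear covariate {name!r}")
            log.warning("scale_and_regress: dropping collinear covariate %r", name)
    X = X[:, keep]

    Y = norm.dense(genes)  # genes x cells
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y - (X @ beta).T
    resid -= resid.mean(axis=1, keepdims=True)
    sd = resid.std(axis=1, ddof=1)
    zero = sd <= 1e-12
    sd[zero] = 1.0
    scaled = resid / sd[:, None]
    scaled[zero, :] = 0.0
    np.clip(scaled, -clip, clip, out=scaled)
    return scaled, list(genes)


def run_pca(
    scaled: np.ndarray,
    gene_symbols,
    n_pcs: int = 20,
    seed: int = 0,
) -> PCAResult:
    """PCA of the scaled genes x cells matrix (cells as observations)."""
    n_genes, n_cells = scaled.shape
    if n_pcs > min(n_genes, n_cells) - 1:
        raise ValueError(
            f"n_pcs={n_pcs} too large for {n_genes} genes x {n_cells} cells"
        )
    solver = "full" if min(n_genes, n_cells) < 200 else "randomized"
    pca = PCA(n_components=n_pcs, svd_solver=solver, random_state=seed)
    emb = pca.fit_transform(scaled.T)
    return PCAResult(
        embeddings=emb,
        loadings=pca.components_.T,
        variance_explained=pca.explained_variance_,
        gene_symbols=np.asarray(gene_symbols, dtype=object),
    )
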