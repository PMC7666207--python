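"""Cross-condition alignment via diagonal CCA and quantile subspace warping.

Two conditions (unstimulated vs TCR-stimulated) of the same cell
population differ by a strong global expression shift, so clustering
their merged embedding separates cells by condition rather than subtype.
Diagonal canonical correlation analysis finds per-cell embeddings that
capture the *shared* correlation structure of the two datasets: the
singular vectors of the cross-product of the two standardised expression
matrices (computed on the union of each sample's top variable genes).
Cells whose expression is explained far better by their own sample's PCA
than by the shared CCA space are removed, the per-component value
distributions are aligned across datasets by quantile warping, and the
aligned embedding is clustered jointly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.utils.extmath import randomized_svd

from . import cluster as cl
from .embed import NormalizedMatrix, find_variable_genes

__all__ = [
    "CCAResult",
    "AlignedEmbedding",
    "union_hvgs",
    "run_cca",
    "varexp_filter",
    "align_subspace",
    "joint_cluster_composition",
    "condition_de",
]

log = logging.getLogger(__name__)


@dataclass
class CCAResult:
    embeddings_a: np.ndarray       # cells_A x n_cc
    embeddings_b: np.ndarray       # cells_B x n_cc
    correlations: np.ndarray       # per component, in [0,1], non-increasing
    genes: list
    barcodes_a: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))
    barcodes_b: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))


@dataclass
class AlignedEmbedding:
    embedding: np.ndarray          # all cells x n_cc
    dataset: np.ndarray            # origin tag per cell
    barcodes: np.ndarray


def union_hvgs(
    norm_a: NormalizedMatrix,
    norm_b: NormalizedMatrix,
    top_n: int = 2000,
    n_cc: int = 25,
) -> list:
    """Union of each sample's top-``top_n`` genes by scaled dispersion,
    restricted to genes present in both samples."""
    shared = set(norm_a.gene_symbols) & set(norm_b.gene_symbols)
    genes: list = []
    for norm in (norm_a, norm_b):
        _, stats = find_variable_genes(norm)
        ranked = (
            stats[np.isfinite(stats["scaled_dispersion"])]
            .sort_values("scaled_dispersion", ascending=False)
            .index
        )
        top = [g for g in ranked if g in shared][:top_n]
        genes.extend(g for g in top if g not in set(genes))
    if len(genes) < n_cc:
        raise ValueError(
            f"union of variable genes ({len(genes)}) smaller than n_cc ({n_cc})"
        )
    return genes


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd[sd <= 1e-12] = 1.0
    return (x - mu) / sd


def run_cca(
    norm_a: NormalizedMatrix,
    norm_b: NormalizedMatrix,
    genes,
    n_cc: int = 25,
    seed: int = 0,
) -> CCAResult:
    """Diagonal CCA of two samples on a common gene set.

    Both matrices are restricted to ``genes`` and row-standardised; the
    left/right singular vectors of the cells_A x cells_B cross-product
    give the per-cell canonical embeddings. Canonical correlations are the
    gene-space correlations of the paired canonical variates, sorted
    non-increasing.
    """
    if n_cc > min(norm_a.n_cells, norm_b.n_cells):
        raise ValueError("n_cc exceeds the smaller dataset's cell count")
    A = _standardize_rows(norm_a.dense(genes))  # genes x cells_A
    B = _standardize_rows(norm_b.dense(genes))
    M = A.T @ B
    U, s, Vt = randomized_svd(M, n_components=n_cc, random_state=seed)
    av = A @ U          # genes x n_cc canonical variates of A
    bv = B @ Vt.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cors = np.abs(
            np.einsum("gk,gk->k", av, bv)
            / (np.linalg.norm(av, axis=0) * np.linalg.norm(bv, axis=0))
        )
    cors = np.clip(np.nan_to_num(cors), 0.0, 1.0)
    order = np.argsort(-cors, kind="stable")
    return CCAResult(
        embeddings_a=U[:, order],
        embeddings_b=Vt.T[:, order],
        correlations=cors[order],
        genes=list(genes),
        barcodes_a=norm_a.barcodes.copy(),
        barcodes_b=norm_b.barcodes.copy(),
    )


def _varexp(profiles: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Fraction of each column's variance explained by the column space of
    ``basis`` (genes x k)."""
    q, _ = np.linalg.qr(basis)
    proj = q.T @ profiles
    num = (proj**2).sum(axis=0)
    den = (profiles**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, 0.0)


def varexp_filter(
    cca: CCAResult,
    norm_a: NormalizedMatrix,
    norm_b: NormalizedMatrix,
    pca_loadings_a: np.ndarray,
    pca_loadings_b: np.ndarray,
    fold: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Keep cells whose PCA-explained variance is at most ``fold`` times
    their CCA-explained variance.

    Per cell, explained variance is the squared norm of the projection of
    its standardised expression profile (over the CCA gene set) onto each
    embedding's gene-space basis, relative to the profile's total sum of
    squares. Cells with zero variance are removed with a warning. Returns
    boolean keep-masks for the two datasets.
    """
    masks = []
    for norm, emb, load in (
        (norm_a, cca.embeddings_a, pca_loadings_a),
        (norm_b, cca.embeddings_b, pca_loadings_b),
    ):
        X = _standardize_rows(norm.dense(cca.genes))  # genes x cells
        cca_basis = X @ emb                            # gene-space canonical directions
        ve_cca = _varexp(X, cca_basis)
        ve_pca = _varexp(X, load)
        zero = (X**2).sum(axis=0) <= 1e-12
        if zero.any():
            warnings.warn(f"removing {int(zero.sum())} zero-variance cells")
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(ve_cca > 0, ve_pca / np.maximum(ve_cca, 1e-12), np.inf)
        keep = (~zero) & (ratio <= fold)
        masks.append(keep)
        log.info("varexp_filter: keeping %d/%d cells", int(keep.sum()), len(keep))
    return masks[0], masks[1]


def align_subspace(cca: CCAResult, n_cc: int | None = None) -> AlignedEmbedding:
    """Quantile-warp dataset B's components onto dataset A's distributions.

    Per component, the smaller dataset's values are monotonically mapped
    onto the larger dataset's empirical quantiles, which preserves
    within-dataset rank order exactly and matches the two per-component
    distributions. Constant components are left unchanged with a warning.
    """
    if n_cc is None:
        n_cc = cca.embeddings_a.shape[1]
    a = cca.embeddings_a[:, :n_cc].copy()
    b = cca.embeddings_b[:, :n_cc].copy()
    if len(a) >= len(b):
        big, small = a, b
    else:
        big, small = b, a
    for j in range(n_cc):
        ref, src = big[:, j], small[:, j]
        if np.ptp(src) <= 1e-15 or np.ptp(ref) <= 1e-15:
            warnings.warn(f"component {j} constant; left unaligned")
            continue
        # empirical quantile of each source value, mapped through the
        # reference quantile function; with equal sizes and identical
        # distributions this is exactly the identity
        order = np.argsort(src, kind="stable")
        ranks = np.empty(len(src))
        ranks[order] = np.arange(len(src)) / (len(src) - 1)
        small[:, j] = np.quantile(ref, ranks)
    emb = np.vstack([a, b])
    dataset = np.array(
        ["a"] * len(cca.embeddings_a) + ["b"] * len(cca.embeddings_b), dtype=object
    )
    barcodes = np.concatenate([cca.barcodes_a, cca.barcodes_b])
    return AlignedEmbedding(emb, dataset, barcodes)


def joint_cluster_composition(
    aligned: AlignedEmbedding,
    condition_of: pd.Series,
    resolution: float = 1.0,
    seed: int = 0,
    snn_k: int = 30,
    snn_prune: float = 1 / 15,
) -> tuple[cl.ClusterLabels, pd.DataFrame]:
    """Cluster the aligned embedding and tabulate per-cluster condition mix."""
    k = min(snn_k, len(aligned.barcodes) - 1)
    graph = cl.build_snn_graph(aligned.embedding, k=k, prune=snn_prune)
    labels = cl.louvain_cluster(graph, resolution=resolution, seed=seed, barcodes=aligned.barcodes)
    cond = condition_of.reindex(labels.barcodes).to_numpy()
    rows = []
    for cid in sorted(np.unique(labels.labels)):
        mask = labels.labels == cid
        counts = pd.Series(cond[mask]).value_counts()
        for condition, n in counts.items():
            rows.append(
                {
                    "cluster": cid,
                    "condition": condition,
                    "n": int(n),
                    "proportion": float(n / mask.sum()),
                }
            )
    return labels, pd.DataFrame(rows)


def condition_de(
    norm: NormalizedMatrix,
    condition_of: pd.Series,
    cluster_labels: cl.ClusterLabels | None = None,
    group: str = "stimulated",
    reference: str = "unstimulated",
    min_frac: float = 0.1,
    min_logfc: float = 0.25,
    alpha: float = 0.05,
) -> dict:
    """Stimulation-response differential expression, overall and per cluster.

    Returns ``{"up": table, "down": table, "per_cluster": table}`` where
    up/down split the overall significant genes by the sign of the log
    fold-change, and the per-cluster table repeats the test within each
    cluster containing both conditions (others are skipped with a log
    entry).
    """
    cond = condition_of.reindex(norm.barcodes)
    overall = cl.rank_markers(norm, cond, group, reference, min_frac, min_logfc)
    sig = overall[overall["p_adj"] < alpha]
    up = sig[sig["logfc"] > 0].reset_index(drop=True)
    down = sig[sig["logfc"] < 0].reset_index(drop=True)

    per_cluster_tables = []
    if cluster_labels is not None:
        series = cluster_labels.as_series()
        for cid in sorted(pd.unique(series)):
            cells = series[series == cid].index
            sub_cond = cond.loc[cond.index.intersection(cells)]
            if sub_cond.nunique() < 2:
                log.info("cluster %s has a single condition; skipped", cid)
                continue
            mask = np.isin(norm.barcodes, cells.to_numpy())
            sub_norm = NormalizedMatrix(
                norm.matrix[:, np.flatnonzero(mask)],
                norm.gene_symbols,
                norm.barcodes[mask],
                norm.scale_factor,
            )
            t = cl.rank_markers(sub_norm, cond, group, reference, min_frac, min_logfc)
            t.insert(0, "cluster", cid)
            per_cluster_tables.append(t)
    per_cluster = (
        pd.concat(per_cluster_tables, ignore_index=True)
        if per_cluster_tables
        else pd.DataFrame()
    )
    return {"up": up, "down": down, "overall": overall, "per_cluster": per_cluster}
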