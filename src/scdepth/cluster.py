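"""Graph-based clustering, marker testing, merging and lineage filtering.

Cells are clustered by modularity optimisation (Louvain) on a shared
nearest-neighbour (SNN) graph built in PC space. Cluster post-processing
follows the benchmark's rules: clusters with too few pairwise
differentially expressed genes are merged, and clusters lacking CD4/CD3
lineage expression (non-T-cell contaminants) are excluded before any
downstream accuracy evaluation.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd
import scipy.stats
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors
import scipy.sparse as sp

from .containers import CountMatrix
from .embed import NormalizedMatrix

__all__ = [
    "ClusterLabels",
    "build_snn_graph",
    "louvain_cluster",
    "rank_markers",
    "merge_similar_clusters",
    "exclude_nontarget_clusters",
    "run_tsne",
    "DEFAULT_REQUIRED_MARKERS",
]

log = logging.getLogger(__name__)

DEFAULT_REQUIRED_MARKERS = ("CD4", "CD3D", "CD3E", "CD3G")


@dataclass
class ClusterLabels:
    """Per-barcode cluster assignment; ids contiguous from 0."""

    labels: np.ndarray
    barcodes: np.ndarray
    provenance: str = "raw"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if self.labels.shape != self.barcodes.shape:
            raise ValueError("labels and barcodes must align")
        ids = np.unique(self.labels)
        if len(ids) and not np.array_equal(ids, np.arange(len(ids))):
            raise ValueError("cluster ids must be contiguous from 0")

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=pd.Index(self.barcodes, name="barcode"), name="cluster")

    def frequencies(self) -> pd.Series:
        return self.as_series().value_counts(normalize=True).sort_index()


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    ids, counts = np.unique(labels, return_counts=True)
    order = ids[np.lexsort((ids, -counts))]
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[v] for v in labels], dtype=int)


def build_snn_graph(embeddings: np.ndarray, k: int = 30, prune: float = 1 / 15) -> ig.Graph:
    """Shared-nearest-neighbour graph in PC space.

    Neighbour sets are the k nearest cells (Euclidean, self included);
    edge weights are the Jaccard overlap of neighbour sets and edges with
    weight below ``prune`` are removed.
    """
    embeddings = np.asarray(embeddings, dtype=float)
    n = embeddings.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k).fit(embeddings)
    idx = nn.kneighbors(return_distance=False)  # excludes self
    rows = np.repeat(np.arange(n), k - 1)
    adj = sp.csr_matrix(
        (np.ones(n * (k - 1)), (rows, idx[:, : k - 1].ravel())), shape=(n, n)
    )
    adj += sp.eye(n, format="csr")  # neighbour set includes the cell itself
    shared = (adj @ adj.T).tocoo()  # |intersection| for pairs sharing neighbours
    mask = shared.row < shared.col
    r, c, inter = shared.row[mask], shared.col[mask], shared.data[mask]
    jaccard = inter / (2 * k - inter)
    keep = jaccard >= prune
    g = ig.Graph(
        n=n,
        edges=list(zip(r[keep].tolist(), c[keep].tolist())),
        edge_attrs={"weight": jaccard[keep].tolist()},
    )
    return g


def louvain_cluster(
    graph: ig.Graph, resolution: float = 1.0, seed: int = 0, barcodes=None,
    method: str = "louvain",
) -> ClusterLabels:
    """Modularity clustering of the SNN graph (Louvain by default).

    Deterministic for a given seed; isolated vertices become singleton
    communities. Cluster ids are relabelled by decreasing size.
    Barcodes are attached by the caller (vertex order = cell order).
    ``method="leiden"`` swaps in the Leiden refinement of Louvain.
    """
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    n_isolated = sum(1 for d in graph.degree() if d == 0)
    if n_isolated:
        log.info("louvain_cluster: %d isolated vertices become singletons", n_isolated)
    weights = "weight" if graph.ecount() else None
    if method == "leiden":
        import leidenalg

        part = leidenalg.find_partition(
            graph,
            leidenalg.RBConfigurationVertexPartition,
            weights=weights,
            resolution_parameter=resolution,
            seed=seed,
            n_iterations=2,
        )
    elif method == "louvain":
        ig.set_random_number_generator(random.Random(seed))
        part = graph.community_multilevel(weights=weights, resolution=resolution)
    else:
        raise ValueError(f"unknown clustering method: {method!r}")
    labels = _relabel_by_size(np.asarray(part.membership))
    if barcodes is None:
        barcodes = np.arange(graph.vcount()).astype(object)
    return ClusterLabels(labels, np.asarray(barcodes, dtype=object), "raw")


def _group_stats(dense: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sub = dense[:, mask]
    frac = (sub > 0).mean(axis=1)
    mean_bt = np.expm1(sub).mean(axis=1)
    return frac, mean_bt


def rank_markers(
    norm: NormalizedMatrix,
    labels: pd.Series,
    group,
    reference_group="rest",
    min_frac: float = 0.1,
    min_logfc: float = 0.25,
) -> pd.DataFrame:
    """Wilcoxon rank-sum marker test of ``group`` against a reference.

    Genes are prefiltered: expressed in at least ``min_frac`` of either
    group and absolute natural-log fold-change (of back-transformed means,
    with pseudocount 1) at least ``min_logfc``. P-values from the
    two-sided rank-sum test, Bonferroni-adjusted over ALL genes on the
    gene axis (the prefilter selects extreme genes, so adjusting only
    over tested genes would be anti-conservative).
    Returns a table sorted by p-value (possibly empty).
    """
    labels = labels.reindex(norm.barcodes)
    in_group = (labels == group).to_numpy()
    if reference_group == "rest":
        in_ref = ~in_group & labels.notna().to_numpy()
    else:
        in_ref = (labels == reference_group).to_numpy()
    if not in_group.any() or not in_ref.any():
        raise ValueError("both groups must be non-empty")
    dense = np.asarray(norm.matrix.todense())
    return _rank_markers_dense(
        dense, norm.gene_symbols, in_group, in_ref, min_frac, min_logfc
    )


def _rank_markers_dense(
    dense: np.ndarray,
    gene_symbols: np.ndarray,
    in_group: np.ndarray,
    in_ref: np.ndarray,
    min_frac: float,
    min_logfc: float,
) -> pd.DataFrame:
    frac1, mean1 = _group_stats(dense, in_group)
    frac2, mean2 = _group_stats(dense, in_ref)
    logfc = np.log1p(mean1) - np.log1p(mean2)
    tested = ((frac1 >= min_frac) | (frac2 >= min_frac)) & (np.abs(logfc) >= min_logfc)
    if not tested.any():
        return _empty_marker_table()
    x = dense[tested][:, in_group]
    y = dense[tested][:, in_ref]
    res = scipy.stats.mannwhitneyu(
        x, y, axis=1, alternative="two-sided", method="asymptotic"
    )
    p = np.asarray(res.pvalue)
    n_genes = dense.shape[0]
    out = pd.DataFrame(
        {
            "gene": np.asarray(gene_symbols, dtype=object)[tested],
            "logfc": logfc[tested],
            "frac_1": frac1[tested],
            "frac_2": frac2[tested],
            "p_value": p,
            "p_adj": np.minimum(p * n_genes, 1.0),
        }
    )
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)


def _empty_marker_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["gene", "logfc", "frac_1", "frac_2", "p_value", "p_adj"]
    )


def rank_all_markers(norm: NormalizedMatrix, labels: pd.Series, **kw) -> pd.DataFrame:
    """Markers of every cluster against the rest, concatenated."""
    tables = []
    for cid in sorted(pd.unique(labels.dropna())):
        t = rank_markers(norm, labels, cid, **kw)
        t.insert(0, "cluster", cid)
        tables.append(t)
    return pd.concat(tables, ignore_index=True) if tables else _empty_marker_table()


def _n_de_genes_dense(
    dense: np.ndarray,
    gene_symbols: np.ndarray,
    in_a: np.ndarray,
    in_b: np.ndarray,
    alpha: float,
    min_logfc: float,
) -> int:
    table = _rank_markers_dense(dense, gene_symbols, in_a, in_b, 0.1, min_logfc)
    if table.empty:
        return 0
    return int((table["p_adj"] < alpha).sum())


def merge_similar_clusters(
    labels: ClusterLabels,
    norm: NormalizedMatrix,
    max_de_genes: int = 10,
    alpha: float = 0.05,
    min_logfc: float = 0.25,
) -> ClusterLabels:
    """Iteratively merge cluster pairs with fewer than ``max_de_genes``
    differentially expressed genes (adjusted p < ``alpha``,
    |logFC| >= ``min_logfc``), fewest-DE pair first."""
    if not np.array_equal(labels.barcodes, norm.barcodes):
        raise ValueError("labels and normalized matrix must cover the same cells in order")
    current = labels.labels.copy()
    if max_de_genes <= 0 or len(np.unique(current)) < 2:
        return ClusterLabels(current, labels.barcodes, "merged")
    dense = np.asarray(norm.matrix.todense())
    while len(np.unique(current)) >= 2:
        ids = sorted(np.unique(current))
        best = None
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                n_de = _n_de_genes_dense(
                    dense, norm.gene_symbols, current == a, current == b, alpha, min_logfc
                )
                if best is None or n_de < best[0]:
                    best = (n_de, a, b)
        n_de, a, b = best
        if n_de >= max_de_genes:
            break
        log.info("merging clusters %d and %d (%d DE genes)", a, b, n_de)
        current[current == b] = a
        uniq = {old: new for new, old in enumerate(sorted(np.unique(current)))}
        current = np.array([uniq[v] for v in current], dtype=int)
    return ClusterLabels(_relabel_by_size(current), labels.barcodes, "merged")


def exclude_nontarget_clusters(
    labels: ClusterLabels,
    cm: CountMatrix,
    required_markers=DEFAULT_REQUIRED_MARKERS,
    min_expressing_frac: float = 0.25,
) -> tuple[ClusterLabels, pd.DataFrame]:
    """Drop clusters showing no CD4 expression and scant CD3 expression.

    A cluster is excluded when the fraction of its cells with any CD4
    count is exactly 0 AND the expressing fraction of every CD3 marker is
    below ``min_expressing_frac``. Returns the filtered labels (cells of
    excluded clusters removed, ids relabelled) and a per-cluster report of
    marker expressing fractions with the exclusion decision.
    """
    required_markers = list(required_markers)
    rows = cm.gene_index(required_markers)
    detected = (cm.counts[rows, :] > 0).toarray()  # markers x cells
    series = labels.as_series()
    report_rows = []
    excluded_ids = []
    for cid in sorted(np.unique(labels.labels)):
        mask = labels.labels == cid
        fracs = detected[:, mask].mean(axis=1)
        by_marker = dict(zip(required_markers, fracs))
        cd4_frac = by_marker[required_markers[0]]
        others = [by_marker[m] for m in required_markers[1:]]
        drop = cd4_frac == 0 and all(f < min_expressing_frac for f in others)
        if drop:
            excluded_ids.append(cid)
        report_rows.append({"cluster": cid, **by_marker, "excluded": drop})
    report = pd.DataFrame(report_rows)
    if len(excluded_ids) == labels.n_clusters:
        raise ValueError("all clusters would be excluded as non-target")
    keep_mask = ~np.isin(labels.labels, excluded_ids)
    kept = labels.labels[keep_mask]
    remap = {old: new for new, old in enumerate(sorted(np.unique(kept)))}
    new_labels = np.array([remap[v] for v in kept], dtype=int)
    if excluded_ids:
        log.info("excluded non-target clusters: %s", excluded_ids)
    return (
        ClusterLabels(new_labels, labels.barcodes[keep_mask], "filtered"),
        report,
    )


def run_tsne(embeddings: np.ndarray, seed: int = 0, perplexity: float = 30.0) -> np.ndarray:
    """2-D tSNE layout of the PC embedding (for reports only)."""
    embeddings = np.asarray(embeddings, dtype=float)
    n = embeddings.shape[0]
    if n < 10:
        raise ValueError("run_tsne needs at least 10 cells")
    perplexity = min(perplexity, (n - 1) / 3)
    ts = TSNE(
        n_components=2, random_state=seed, init="pca", perplexity=perplexity
    )
    return ts.fit_transform(embeddings)
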