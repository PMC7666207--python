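"""SNN graph, Louvain clustering, marker tests, merging and exclusion."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

import scdepth
from scdepth import CountMatrix
from scdepth.cluster import (
    ClusterLabels,
    build_snn_graph,
    exclude_nontarget_clusters,
    louvain_cluster,
    merge_similar_clusters,
    rank_markers,
    run_tsne,
)
from scdepth.embed import NormalizedMatrix, log_normalize


def _norm(dense, genes=None):
    dense = np.asarray(dense, dtype=float)
    genes = genes or [f"G{i}" for i in range(dense.shape[0])]
    return NormalizedMatrix(
        sp.csr_matrix(dense),
        np.array(genes, dtype=object),
        np.array([f"B{i}" for i in range(dense.shape[1])], dtype=object),
    )


class TestSNNGraph:
    def test_far_separated_clouds_have_no_cross_edges(self, rng):
        a = rng.normal(0, 1, size=(40, 3))
        b = rng.normal(0, 1, size=(40, 3)) + 1000
        g = build_snn_graph(np.vstack([a, b]), k=10)
        for e in g.es:
            assert (e.source < 40) == (e.target < 40)

    def test_full_neighbourhood_zero_prune_is_complete(self, rng):
        x = rng.normal(0, 1, size=(12, 2))
        g = build_snn_graph(x, k=11, prune=0.0)
        assert g.ecount() == 12 * 11 // 2

    def test_jaccard_weights_match_hand_computation(self):
        # neighbour sets (k=2, incl. self): {0,1}, {1,0}, {2,1}, {3,2}
        x = np.array([[0.0], [1.0], [3.0], [10.0]])
        g = build_snn_graph(x, k=2, prune=0.0)
        w = {tuple(sorted((e.source, e.target))): e["weight"] for e in g.es}
        assert w[(0, 1)] == pytest.approx(1.0)  # identical neighbour sets
        assert w[(1, 2)] == pytest.approx(1 / 3)

    def test_k_must_be_below_cell_count(self, rng):
        with pytest.raises(ValueError, match="k="):
            build_snn_graph(rng.normal(0, 1, size=(5, 2)), k=5)


class TestLouvain:
    def test_two_disconnected_cliques(self):
        import igraph as ig
        g = ig.Graph.Full(10) + ig.Graph.Full(10)
        g.es["weight"] = 1.0
        labels = louvain_cluster(g, seed=0)
        assert labels.n_clusters == 2
        assert len(set(labels.labels[:10])) == 1

    def test_default_scenario_recovers_subtypes(self, default_scenario, default_reference):
        """QC -> embed -> cluster on the default scenario recovers the true
        subtype partition (ARI >= 0.8) with a plausible cluster count."""
        _, _, _, truth = default_scenario
        labels = default_reference.labels
        tr = truth.cells["subtype"].reindex(labels.barcodes)
        ari = adjusted_rand_score(tr.to_numpy(), labels.labels)
        assert ari >= 0.8
        assert 3 <= labels.n_clusters <= 7

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_cluster_count_nondecreasing_in_resolution(self, rng, seed):
        x = np.vstack([rng.normal(i * 3, 1.2, size=(60, 4)) for i in range(3)])
        g = build_snn_graph(x, k=15)
        k_low = louvain_cluster(g, resolution=0.1, seed=seed).n_clusters
        k_high = louvain_cluster(g, resolution=2.0, seed=seed).n_clusters
        assert k_low <= k_high

    def test_deterministic_given_seed(self, rng):
        x = rng.normal(0, 1, size=(100, 5))
        g = build_snn_graph(x, k=10)
        a = louvain_cluster(g, seed=3)
        b = louvain_cluster(g, seed=3)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_leiden_backend_agrees_on_clean_structure(self, rng):
        x = np.vstack([rng.normal(i * 5, 1.0, size=(50, 4)) for i in range(3)])
        g = build_snn_graph(x, k=12)
        louvain = louvain_cluster(g, seed=0)
        leiden = louvain_cluster(g, seed=0, method="leiden")
        assert leiden.n_clusters == louvain.n_clusters == 3
        with pytest.raises(ValueError, match="unknown clustering method"):
            louvain_cluster(g, method="walktrap")


class TestRankMarkers:
    def test_exclusive_gene_is_extremely_significant(self):
        dense = np.zeros((5, 100))
        dense[0, :50] = 2.0  # expressed only in group A
        dense[1:, :] = 1.0
        labels = pd.Series([0] * 50 + [1] * 50,
                           index=[f"B{i}" for i in range(100)])
        t = rank_markers(_norm(dense), labels, 0, 1)
        row = t[t["gene"] == "G0"].iloc[0]
        assert row["p_adj"] < 1e-6
        assert row["frac_1"] == 1.0 and row["frac_2"] == 0.0

    def test_infinite_logfc_filter_empties_result(self, rng):
        dense = rng.random((10, 60))
        labels = pd.Series([0] * 30 + [1] * 30, index=[f"B{i}" for i in range(60)])
        t = rank_markers(_norm(dense), labels, 0, 1, min_logfc=np.inf)
        assert t.empty

    def test_label_permutation_rarely_significant(self, rng):
        # sparse droplet-like null; family-wise error controlled at 5%
        dense = rng.poisson(0.3, size=(300, 120)).astype(float)
        norm = _norm(dense)
        n_sig = 0
        for i in range(20):
            perm = rng.permutation([0] * 60 + [1] * 60)
            labels = pd.Series(perm, index=[f"B{i}" for i in range(120)])
            t = rank_markers(norm, labels, 0, 1)
            n_sig += int(not t.empty and (t["p_adj"] < 0.05).any())
        assert n_sig <= 2


class TestMergeClusters:
    def test_random_split_of_one_population_is_merged(self, rng):
        dense = rng.poisson(2.0, size=(50, 200)).astype(float)
        labels = ClusterLabels(rng.integers(0, 2, 200), np.array([f"B{i}" for i in range(200)], dtype=object))
        merged = merge_similar_clusters(labels, _norm(dense))
        assert merged.n_clusters == 1
        assert merged.provenance == "merged"

    def test_strongly_distinct_clusters_not_merged(self, rng):
        dense = rng.poisson(1.0, size=(300, 200)).astype(float)
        dense[:100, 100:] += rng.poisson(4.0, size=(100, 100))
        labels = ClusterLabels(np.r_[np.zeros(100, int), np.ones(100, int)],
                               np.array([f"B{i}" for i in range(200)], dtype=object))
        merged = merge_similar_clusters(labels, _norm(dense))
        assert merged.n_clusters == 2

    def test_zero_budget_is_identity(self, rng):
        dense = rng.random((20, 50))
        labels = ClusterLabels(rng.integers(0, 3, 50), np.array([f"B{i}" for i in range(50)], dtype=object))
        labels = ClusterLabels(
            pd.factorize(labels.labels)[0], labels.barcodes)
        merged = merge_similar_clusters(labels, _norm(dense), max_de_genes=0)
        np.testing.assert_array_equal(merged.labels, labels.labels)


class TestExcludeNonTarget:
    def _setup(self, rng, contaminant_frac_cd3=0.0):
        genes = ["CD4", "CD3D", "CD3E", "CD3G", "G4"]
        dense = rng.poisson(1.0, size=(5, 60)) + 1
        dense[:4, 40:] = 0  # last 20 cells: no lineage markers
        if contaminant_frac_cd3:
            k = int(20 * contaminant_frac_cd3)
            dense[1, 40:40 + k] = 1
        cm = CountMatrix(sp.csr_matrix(dense), np.array(genes, dtype=object),
                         np.array([f"B{i}" for i in range(60)], dtype=object))
        labels = ClusterLabels(np.r_[np.zeros(40, int), np.ones(20, int)],
                               np.array([f"B{i}" for i in range(60)], dtype=object))
        return cm, labels

    def test_contaminant_cluster_excluded(self, rng):
        cm, labels = self._setup(rng)
        out, report = exclude_nontarget_clusters(labels, cm)
        assert report.loc[report["cluster"] == 1, "excluded"].item()
        assert set(out.barcodes) == {f"B{i}" for i in range(40)}
        assert out.n_clusters == 1

    def test_cd4_expressing_cluster_retained(self, rng):
        cm, labels = self._setup(rng)
        out, report = exclude_nontarget_clusters(labels, cm)
        assert not report.loc[report["cluster"] == 0, "excluded"].item()

    def test_exclusion_monotone_in_threshold(self, rng):
        cm, labels = self._setup(rng, contaminant_frac_cd3=0.5)
        excluded = []
        for frac in (0.1, 0.25, 0.6, 1.0):
            _, report = (
                exclude_nontarget_clusters(labels, cm, min_expressing_frac=frac)
                if frac < 1.0
                else exclude_nontarget_clusters(labels, cm, min_expressing_frac=frac)
            )
            excluded.append(int(report["excluded"].sum()))
        assert excluded == sorted(excluded)

    def test_all_excluded_raises(self, rng):
        cm, labels = self._setup(rng)
        only_contam = ClusterLabels(np.zeros(20, int),
                                    np.array([f"B{i}" for i in range(40, 60)], dtype=object))
        small = cm.subset_cells(np.arange(40, 60))
        with pytest.raises(ValueError, match="all clusters"):
            exclude_nontarget_clusters(only_contam, small)


class TestLabelInvariants:
    def test_transformations_never_invent_barcodes(self, default_reference):
        raw = set(default_reference.labels_raw.barcodes)
        final = set(default_reference.labels.barcodes)
        assert final <= raw

    def test_frequencies_sum_to_retained_cells(self, default_reference):
        labels = default_reference.labels
        assert labels.as_series().value_counts().sum() == len(labels.barcodes)
        assert labels.frequencies().sum() == pytest.approx(1.0)


class TestTSNE:
    def test_output_shape_and_determinism(self, rng):
        x = rng.normal(0, 1, size=(60, 5))
        a = run_tsne(x, seed=1)
        b = run_tsne(x, seed=1)
        assert a.shape == (60, 2)
        np.testing.assert_array_equal(a, b)

    def test_blobs_stay_separated(self, rng):
        x = np.vstack([rng.normal(0, 0.5, (40, 5)), rng.normal(8, 0.5, (40, 5))])
        y = run_tsne(x, seed=0)
        intra = np.linalg.norm(y[:40] - y[:40].mean(0), axis=1).mean()
        inter = np.linalg.norm(y[:40].mean(0) - y[40:].mean(0))
        assert inter > intra

    def test_minimum_cells(self, rng):
        with pytest.raises(ValueError, match="10 cells"):
            run_tsne(rng.random((5, 3)))
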