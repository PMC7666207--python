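"""Diagonal CCA, variance-ratio filtering, alignment and condition DE."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from dataclasses import replace

import scdepth
from scdepth.datagen import GeneratorConfig
from scdepth.embed import NormalizedMatrix, log_normalize, run_pca, scale_and_regress
from scdepth.integrate import (
    align_subspace,
    condition_de,
    joint_cluster_composition,
    run_cca,
    union_hvgs,
    varexp_filter,
)


def _norm(dense, genes=None, prefix="B"):
    dense = np.asarray(dense, dtype=float)
    genes = genes or [f"G{i}" for i in range(dense.shape[0])]
    return NormalizedMatrix(
        sp.csr_matrix(dense),
        np.array(genes, dtype=object),
        np.array([f"{prefix}{i}" for i in range(dense.shape[1])], dtype=object),
    )


@pytest.fixture(scope="module")
def paired_samples():
    """Small paired unstimulated/stimulated scenario."""
    cfg = GeneratorConfig(n_genes=800, n_cells=500, seed=21)
    pair = scdepth.generate_paired_conditions(cfg)
    out = {}
    for cond, (cm, _, truth) in pair.items():
        qc_cm, _ = scdepth.apply_qc(cm)
        out[cond] = (qc_cm, log_normalize(qc_cm), truth)
    return out


class TestUnionHVGs:
    def test_identical_samples_give_exactly_top_n(self, paired_samples):
        _, norm, _ = paired_samples["unstimulated"]
        genes = union_hvgs(norm, norm, top_n=100, n_cc=10)
        assert len(genes) == 100

    def test_paired_samples_give_between_n_and_2n(self, paired_samples):
        _, norm_u, _ = paired_samples["unstimulated"]
        _, norm_s, _ = paired_samples["stimulated"]
        genes = union_hvgs(norm_u, norm_s, top_n=200, n_cc=10)
        assert 200 < len(genes) <= 400

    def test_too_small_union_rejected(self, paired_samples):
        _, norm, _ = paired_samples["unstimulated"]
        with pytest.raises(ValueError, match="n_cc"):
            union_hvgs(norm, norm, top_n=5, n_cc=10)


class TestRunCCA:
    def test_duplicate_dataset_has_unit_first_correlation(self, paired_samples):
        _, norm, _ = paired_samples["unstimulated"]
        genes = union_hvgs(norm, norm, top_n=150, n_cc=10)
        cca = run_cca(norm, norm, genes, n_cc=10, seed=0)
        assert cca.correlations[0] >= 0.99

    def test_independent_noise_correlates_less_than_duplicate(self, rng):
        a = _norm(rng.normal(2, 1, size=(100, 80)).clip(0), prefix="A")
        b = _norm(rng.normal(2, 1, size=(100, 80)).clip(0), prefix="B")
        genes = list(a.gene_symbols)
        dup = run_cca(a, a, genes, n_cc=5, seed=0)
        indep = run_cca(a, b, genes, n_cc=5, seed=0)
        assert indep.correlations[0] < dup.correlations[0]

    def test_correlations_sorted_and_bounded(self, paired_samples):
        _, norm_u, _ = paired_samples["unstimulated"]
        _, norm_s, _ = paired_samples["stimulated"]
        genes = union_hvgs(norm_u, norm_s, top_n=200, n_cc=15)
        cca = run_cca(norm_u, norm_s, genes, n_cc=15, seed=0)
        assert ((cca.correlations >= 0) & (cca.correlations <= 1)).all()
        assert (np.diff(cca.correlations) <= 1e-12).all()

    def test_deterministic_given_seed(self, paired_samples):
        _, norm_u, _ = paired_samples["unstimulated"]
        _, norm_s, _ = paired_samples["stimulated"]
        genes = union_hvgs(norm_u, norm_s, top_n=100, n_cc=8)
        a = run_cca(norm_u, norm_s, genes, n_cc=8, seed=3)
        b = run_cca(norm_u, norm_s, genes, n_cc=8, seed=3)
        np.testing.assert_array_equal(a.embeddings_a, b.embeddings_a)

    def test_excessive_components_rejected(self, rng):
        a = _norm(rng.random((20, 10)))
        with pytest.raises(ValueError, match="n_cc"):
            run_cca(a, a, list(a.gene_symbols), n_cc=11)


def _pca_loadings(norm, genes, n_pcs=10):
    dense = norm.dense(genes)
    mu = dense.mean(axis=1, keepdims=True)
    sd = dense.std(axis=1, ddof=1, keepdims=True)
    sd[sd <= 1e-12] = 1.0
    res = run_pca((dense - mu) / sd, genes, n_pcs=n_pcs)
    return res.loadings


class TestVarexpFilter:
    def test_duplicate_datasets_keep_nearly_all_cells(self, paired_samples):
        _, norm, _ = paired_samples["unstimulated"]
        genes = union_hvgs(norm, norm, top_n=150, n_cc=10)
        cca = run_cca(norm, norm, genes, n_cc=10, seed=0)
        load = _pca_loadings(norm, genes)
        keep_a, keep_b = varexp_filter(cca, norm, norm, load, load, fold=2.0)
        assert keep_a.mean() >= 0.95 and keep_b.mean() >= 0.95

    def test_infinite_fold_keeps_everyone(self, paired_samples):
        _, norm_u, _ = paired_samples["unstimulated"]
        _, norm_s, _ = paired_samples["stimulated"]
        genes = union_hvgs(norm_u, norm_s, top_n=150, n_cc=10)
        cca = run_cca(norm_u, norm_s, genes, n_cc=10, seed=0)
        keep_a, keep_b = varexp_filter(
            cca, norm_u, norm_s,
            _pca_loadings(norm_u, genes), _pca_loadings(norm_s, genes),
            fold=np.inf,
        )
        assert keep_a.all() and keep_b.all()

    def test_dataset_private_signal_is_filtered(self, rng):
        """Cells dominated by a gene block absent from the other dataset
        load on PCA but not on the shared CCA space."""
        n_genes, n_cells, n_latent = 120, 150, 10
        # genes 0-99 load on a latent structure shared by both datasets;
        # genes 100-119 are pure noise in both
        latent = rng.normal(0, 1, size=(n_latent, n_cells))
        loadings = rng.normal(0, 1, size=(100, n_latent))
        a = np.vstack([loadings @ latent, np.zeros((20, n_cells))])
        b = a + rng.normal(0, 0.3, size=a.shape)
        a = a + rng.normal(0, 0.3, size=a.shape)
        # private block: 20 cells of A dominated by the noise-only genes
        a[100:, :20] += 8
        norm_a, norm_b = _norm(a, prefix="A"), _norm(b, prefix="B")
        genes = list(norm_a.gene_symbols)
        cca = run_cca(norm_a, norm_b, genes, n_cc=10, seed=0)
        keep_a, _ = varexp_filter(
            cca, norm_a, norm_b,
            _pca_loadings(norm_a, genes), _pca_loadings(norm_b, genes),
            fold=2.0,
        )
        assert keep_a[:20].mean() < keep_a[20:].mean()
        assert (~keep_a[:20]).any()


class TestAlignSubspace:
    def _cca_like(self, a, b):
        from scdepth.integrate import CCAResult
        return CCAResult(
            embeddings_a=a, embeddings_b=b,
            correlations=np.linspace(1, 0.5, a.shape[1]),
            genes=[],
            barcodes_a=np.array([f"A{i}" for i in range(len(a))], dtype=object),
            barcodes_b=np.array([f"B{i}" for i in range(len(b))], dtype=object),
        )

    def test_identical_distributions_warp_is_identity(self, rng):
        vals = rng.normal(0, 1, size=(200, 3))
        aligned = align_subspace(self._cca_like(vals.copy(), vals.copy()))
        np.testing.assert_allclose(aligned.embedding[:200], vals, atol=1e-6)
        np.testing.assert_allclose(aligned.embedding[200:], vals, atol=1e-6)

    def test_shift_is_removed(self, rng):
        a = rng.normal(0, 1, size=(300, 2))
        b = a[:250].copy()
        b[:, 0] += 5.0
        aligned = align_subspace(self._cca_like(a, b))
        out_b = aligned.embedding[300:]
        for q in np.linspace(0.1, 0.9, 9):
            diff = np.quantile(out_b[:, 0], q) - np.quantile(a[:, 0], q)
            assert abs(diff) < 0.05 * a[:, 0].std()

    def test_rank_order_preserved(self, rng):
        a = rng.normal(0, 1, size=(200, 2))
        b = rng.normal(3, 2, size=(150, 2))
        aligned = align_subspace(self._cca_like(a, b))
        out_b = aligned.embedding[200:]
        for j in range(2):
            assert (np.argsort(out_b[:, j], kind="stable")
                    == np.argsort(b[:, j], kind="stable")).all()

    def test_never_mixes_barcodes_or_counts(self, rng):
        a = rng.normal(0, 1, size=(40, 2))
        b = rng.normal(0, 1, size=(30, 2))
        aligned = align_subspace(self._cca_like(a, b))
        assert (aligned.dataset[:40] == "a").all()
        assert (aligned.dataset[40:] == "b").all()
        assert len(aligned.barcodes) == 70


class TestJointComposition:
    def test_proportions_sum_to_one(self, rng):
        from scdepth.integrate import AlignedEmbedding
        emb = np.vstack([rng.normal(0, 1, (100, 4)), rng.normal(6, 1, (100, 4))])
        barcodes = np.array([f"C{i}" for i in range(200)], dtype=object)
        aligned = AlignedEmbedding(emb, np.array(["a"] * 100 + ["b"] * 100, dtype=object), barcodes)
        cond = pd.Series(rng.choice(["u", "s"], 200), index=barcodes)
        labels, comp = joint_cluster_composition(aligned, cond, snn_k=15, seed=0)
        sums = comp.groupby("cluster")["proportion"].sum()
        np.testing.assert_allclose(sums, 1.0)

    def test_condition_private_population_dominates_its_cluster(self, rng):
        """A subtype present in one condition only yields a cluster
        overwhelmingly from that condition."""
        from scdepth.integrate import AlignedEmbedding
        shared_u = rng.normal(0, 1, (120, 4))
        shared_s = rng.normal(0, 1, (120, 4))
        private_u = rng.normal(10, 1, (60, 4))
        emb = np.vstack([shared_u, private_u, shared_s])
        barcodes = np.array([f"C{i}" for i in range(300)], dtype=object)
        cond = pd.Series(["u"] * 180 + ["s"] * 120, index=barcodes)
        aligned = AlignedEmbedding(emb, np.array(["a"] * 180 + ["b"] * 120, dtype=object), barcodes)
        labels, comp = joint_cluster_composition(aligned, cond, snn_k=15, seed=0)
        private_ids = set(labels.labels[120:180])
        top = comp[comp["cluster"].isin(private_ids) & (comp["condition"] == "u")]
        assert (top["proportion"] >= 0.8).all()


class TestConditionDE:
    def test_boosted_genes_recovered_as_upregulated(self, paired_samples):
        cm_u, norm_u, truth_u = paired_samples["unstimulated"]
        cm_s, norm_s, _ = paired_samples["stimulated"]
        shared = sorted(set(norm_u.gene_symbols) & set(norm_s.gene_symbols))
        iu, isx = norm_u.gene_index(shared), norm_s.gene_index(shared)
        merged = NormalizedMatrix(
            sp.hstack([norm_u.matrix[iu], norm_s.matrix[isx]]).tocsr(),
            np.array(shared, dtype=object),
            np.concatenate([norm_u.barcodes, norm_s.barcodes]),
        )
        cond = pd.Series(
            ["unstimulated"] * norm_u.n_cells + ["stimulated"] * norm_s.n_cells,
            index=merged.barcodes,
        )
        res = condition_de(merged, cond)
        up_genes = set(res["up"]["gene"])
        # boosted genes that the assay can see (expressed in >= 10% of
        # stimulated cells, i.e. passing the test's own prefilter) should
        # be recovered almost in full
        stim_frac = (np.asarray(merged.matrix.todense()) > 0)[
            :, norm_u.n_cells:
        ].mean(axis=1)
        frac_of = dict(zip(merged.gene_symbols, stim_frac))
        testable = [g for g in truth_u.stim_up if frac_of.get(g, 0) >= 0.1]
        assert len(testable) >= 20
        recovered = sum(1 for g in testable if g in up_genes)
        assert recovered >= 0.8 * len(testable)
        assert len(res["down"]) > 0

    def test_permuted_conditions_rarely_significant(self, rng):
        dense = rng.poisson(0.3, size=(300, 160)).astype(float)
        norm = _norm(dense)
        n_hits = 0
        for i in range(20):
            cond = pd.Series(rng.permutation(["stimulated"] * 80 + ["unstimulated"] * 80),
                             index=norm.barcodes)
            res = condition_de(norm, cond)
            n_hits += int(len(res["up"]) + len(res["down"]) > 0)
        assert n_hits <= 2

    def test_single_condition_cluster_skipped(self, rng):
        dense = rng.poisson(1.0, size=(30, 40)).astype(float)
        norm = _norm(dense)
        cond = pd.Series(["stimulated"] * 20 + ["unstimulated"] * 20, index=norm.barcodes)
        from scdepth.cluster import ClusterLabels
        labels = ClusterLabels(np.r_[np.zeros(20, int), np.ones(20, int)], norm.barcodes)
        res = condition_de(norm, cond, cluster_labels=labels)
        assert res["per_cluster"].empty
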