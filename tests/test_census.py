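"""Receptor census vs dense-loop oracles and an independent scanpy route."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from periphoton.census import (
    GeneNotFound,
    coexpression,
    count_positive,
    dotplot_stats,
)
from periphoton.synth import generate_counts


@pytest.fixture
def toy():
    # genes x cells, 3 genes x 5 cells
    genes = ["Hcrtr1", "Hcrtr2", "Oxtr"]
    m = sparse.csr_matrix(np.array([
        [0, 1, 0, 3, 2],
        [5, 0, 0, 1, 0],
        [1, 1, 1, 1, 1],
    ]))
    labels = np.array(["D1", "D1", "IN", "IN", "IN"])
    return m, genes, labels


@pytest.fixture
def random_matrix(rng):
    genes = [f"g{i}" for i in range(40)]
    dense = rng.poisson(0.3, size=(40, 300))
    labels = rng.choice(["D1", "D2", "IN", "Astro"], size=300)
    return sparse.csr_matrix(dense), genes, labels, dense


class TestCountPositive:
    def test_toy_counts(self, toy):
        m, genes, _ = toy
        assert count_positive(m, genes, "Hcrtr1") == 3
        assert count_positive(m, genes, "Hcrtr2") == 2
        assert count_positive(m, genes, "Oxtr") == 5

    def test_all_zero_gene(self):
        m = sparse.csr_matrix(np.zeros((1, 4)))
        assert count_positive(m, ["g"], "g") == 0

    def test_absent_gene_named(self, toy):
        m, genes, _ = toy
        with pytest.raises(GeneNotFound, match="Nope"):
            count_positive(m, genes, "Nope")

    def test_matches_dense_loop_oracle(self, random_matrix):
        m, genes, _, dense = random_matrix
        for gi in (0, 7, 33):
            expected = sum(1 for c in range(dense.shape[1]) if dense[gi, c] > 0)
            assert count_positive(m, genes, genes[gi]) == expected


class TestDotplotStats:
    def test_two_clusters_one_sided_expression_scaled_values(self):
        # gene expressed in one of two clusters: hand computation with
        # values (x, 0) gives mean x/2, sample SD x/sqrt(2), so the scaled
        # pair is (+1/sqrt(2), -1/sqrt(2)) = (+0.707, -0.707)
        genes = ["g"]
        m = sparse.csr_matrix(np.array([[4, 4, 0, 0]]))
        labels = np.array(["A", "A", "B", "B"])
        cen = dotplot_stats(m, genes, labels, ["g"])
        scaled = cen.table.set_index("cluster")["avg_expr_scaled"]
        assert scaled["A"] == pytest.approx(np.sqrt(0.5), rel=1e-9)
        assert scaled["B"] == pytest.approx(-np.sqrt(0.5), rel=1e-9)

    def test_pct_pos_per_cluster(self, toy):
        m, genes, labels = toy
        cen = dotplot_stats(m, genes, labels, ["Hcrtr1"])
        row_d1 = cen.lookup("Hcrtr1", "D1")
        row_in = cen.lookup("Hcrtr1", "IN")
        assert row_d1["n_pos"] == 1 and row_d1["pct_pos"] == pytest.approx(50.0)
        assert row_in["n_pos"] == 2 and row_in["pct_pos"] == pytest.approx(
            100.0 * 2 / 3)

    def test_single_cluster_scaled_zero_with_flag(self, toy):
        m, genes, _ = toy
        cen = dotplot_stats(m, genes, np.array(["D1"] * 5), ["Hcrtr1"])
        assert cen.single_cluster
        assert (cen.table["avg_expr_scaled"] == 0.0).all()

    def test_all_zero_gene_zero_everywhere(self):
        m = sparse.csr_matrix(np.array([[0, 0, 0, 0], [1, 2, 3, 4]]))
        cen = dotplot_stats(m, ["dead", "alive"], np.array(["A", "A", "B", "B"]),
                            ["dead"])
        assert (cen.table["pct_pos"] == 0.0).all()

    def test_matches_dense_loop_oracle(self, random_matrix):
        m, genes, labels, dense = random_matrix
        cen = dotplot_stats(m, genes, labels, ["g3", "g11"])
        totals = dense.sum(axis=0)
        for gene in ("g3", "g11"):
            gi = genes.index(gene)
            logn = np.array([
                np.log1p(1e4 * dense[gi, c] / totals[c]) if totals[c] else 0.0
                for c in range(dense.shape[1])
            ])
            means = {}
            for cl in np.unique(labels):
                cells = np.where(labels == cl)[0]
                n_pos = sum(1 for c in cells if dense[gi, c] > 0)
                row = cen.lookup(gene, cl)
                assert row["n_pos"] == n_pos
                assert row["pct_pos"] == pytest.approx(
                    100.0 * n_pos / len(cells), rel=1e-12)
                means[cl] = logn[cells].mean()
            mv = np.array([means[cl] for cl in means])
            for j, cl in enumerate(means):
                expected = (mv[j] - mv.mean()) / mv.std(ddof=1)
                assert cen.lookup(gene, cl)["avg_expr_scaled"] == pytest.approx(
                    expected, rel=1e-8)

    def test_matches_scanpy_normalization_route(self, random_matrix):
        # independent cross-check of the counts-per-10k log1p average
        # expression through scanpy's normalize_total/log1p
        sc = pytest.importorskip("scanpy")
        import anndata as ad
        m, genes, labels, dense = random_matrix
        adata = ad.AnnData(sparse.csr_matrix(dense.T.astype(np.float32)))
        adata.var_names = genes
        sc.pp.normalize_total(adata, target_sum=1e4)
        sc.pp.log1p(adata)
        x = np.asarray(adata[:, "g5"].X.todense()).ravel()
        cen = dotplot_stats(m, genes, labels, ["g5"])
        for cl in np.unique(labels):
            ours = cen.lookup("g5", cl)["avg_expr"]
            theirs = float(x[labels == cl].mean())
            assert ours == pytest.approx(theirs, rel=1e-5)

    def test_label_length_mismatch_rejected(self, toy):
        m, genes, _ = toy
        with pytest.raises(ValueError, match="labels cover"):
            dotplot_stats(m, genes, np.array(["A", "B"]), ["Hcrtr1"])


class TestCoexpression:
    def test_disjoint_positives(self):
        m = sparse.csr_matrix(np.array([[1, 1, 0, 0], [0, 0, 1, 1]]))
        out = coexpression(m, ["a", "b"], "a", "b")
        assert out["pct_both"] == 0.0
        assert out["pct_a"] == out["pct_b"] == 50.0

    def test_identical_rows(self):
        m = sparse.csr_matrix(np.array([[1, 0, 2, 0], [1, 0, 2, 0]]))
        out = coexpression(m, ["a", "b"], "a", "b")
        assert out["pct_both"] == out["pct_a"] == out["pct_b"] == 50.0

    def test_matches_dense_loop_oracle(self, random_matrix):
        m, genes, _, dense = random_matrix
        out = coexpression(m, genes, "g1", "g2")
        n = dense.shape[1]
        both = sum(1 for c in range(n) if dense[1, c] > 0 and dense[2, c] > 0)
        assert out["pct_both"] == pytest.approx(100.0 * both / n, rel=1e-12)

    def test_both_bounded_by_each(self, random_matrix):
        m, genes, _, _ = random_matrix
        out = coexpression(m, genes, "g8", "g9")
        assert out["pct_both"] <= min(out["pct_a"], out["pct_b"])


class TestInvariances:
    def test_column_permutation_invariance(self, random_matrix, rng):
        m, genes, labels, dense = random_matrix
        perm = rng.permutation(dense.shape[1])
        m2 = sparse.csr_matrix(dense[:, perm])
        a = dotplot_stats(m, genes, labels, ["g0"]).table
        b = dotplot_stats(m2, genes, labels[perm], ["g0"]).table
        a = a.sort_values("cluster").reset_index(drop=True)
        b = b.sort_values("cluster").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_pct_pos_monotone_under_added_counts(self, toy):
        m, genes, labels = toy
        before = dotplot_stats(m, genes, labels, ["Hcrtr2"]).table
        dense = np.asarray(m.todense())
        dense[1, 1] += 1  # a zero cell becomes positive
        after = dotplot_stats(sparse.csr_matrix(dense), genes, labels,
                              ["Hcrtr2"]).table
        merged = before.merge(after, on=["gene", "cluster"],
                              suffixes=("_b", "_a"))
        assert (merged["pct_pos_a"] >= merged["pct_pos_b"]).all()

    def test_cluster_cell_counts_partition_total(self, random_matrix):
        m, genes, labels, _ = random_matrix
        cen = dotplot_stats(m, genes, labels, ["g0"])
        assert cen.table["n_cells"].sum() == cen.total_cells
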