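"""QC, variable-gene selection, embedding, clustering, annotation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score, silhouette_score

import mesotraject as mt
from conftest import toy_matrix


class TestQcFilter:
    def test_read_threshold_is_strict_less_than(self):
        m = toy_matrix([[9_999], [10_000], [10_001]])
        kept, qc = mt.cells.qc_filter(m)
        assert kept.cell_ids == ["c1", "c2"]
        assert qc.loc["c0", "reason"] == "reads"

    def test_mito_threshold_is_strict_greater_than(self):
        counts = np.array([[8_000, 2_000],     # ratio exactly 0.2 -> keep
                           [7_000, 3_000]])    # 0.3 -> drop
        m = toy_matrix(counts, mito=[False, True])
        kept, qc = mt.cells.qc_filter(m)
        assert kept.cell_ids == ["c0"]
        assert qc.loc["c1", "reason"] == "mito"

    def test_planted_failures_removed_exactly(self, cell_data):
        m, truth = cell_data
        kept, qc = mt.cells.qc_filter(m)
        removed = set(qc.index[~qc["pass"]])
        assert removed == set(truth.low_quality_flags)
        assert kept.n_cells == m.n_cells - len(removed)
        assert kept.gene_ids == m.gene_ids

    def test_idempotent(self, cell_data):
        m, _ = cell_data
        once, _ = mt.cells.qc_filter(m)
        twice, qc2 = mt.cells.qc_filter(once)
        assert twice.n_cells == once.n_cells
        assert qc2["pass"].all()

    def test_all_failing_raises_with_reasons(self):
        m = toy_matrix([[5], [7]])
        with pytest.raises(RuntimeError, match="reads"):
            mt.cells.qc_filter(m)


class TestSelectHvg:
    def test_returns_requested_count(self, clean_cells):
        m, _ = clean_cells
        assert len(mt.cells.select_hvg(m, n=50)) == 50

    def test_higher_dispersion_ranks_first(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(5.0, size=(60, 1))
        noisy = rng.poisson(np.where(rng.random(60) < 0.5, 1.0, 9.0))[:, None]
        m = toy_matrix(np.hstack([noisy, base]))   # g0 overdispersed
        assert mt.cells.select_hvg(m, n=1) == ["g0"]

    def test_ties_break_lexicographically(self):
        m = toy_matrix(np.tile([[3, 3, 3]], (10, 1)))
        assert mt.cells.select_hvg(m, n=2) == ["g0", "g1"]

    def test_n_larger_than_genes_rejected(self, clean_cells):
        m, _ = clean_cells
        with pytest.raises(mt.ParameterError):
            mt.cells.select_hvg(m, n=m.n_genes + 1)


def _blobs(n_blobs, per_blob=40, sep=50.0, seed=0):
    rng = np.random.default_rng(seed)
    pts = np.vstack([rng.normal(0, 1, (per_blob, 2)) + sep * np.array(
        [k % 3, k // 3]) for k in range(n_blobs)])
    labels = np.repeat(np.arange(n_blobs), per_blob)
    return pts, labels


class TestEmbedCluster:
    def test_embedding_shape_and_duplicate_rows(self, clean_cells):
        m, _ = clean_cells
        hvg = mt.cells.select_hvg(m, n=80)
        emb = mt.cells.embed_cells(m, hvg, n_pcs=20, seed=0, method="pca")
        assert emb.shape == (m.n_cells, 2)
        dup = toy_matrix(np.vstack([m.counts, m.counts[:1]]))
        emb2 = mt.cells.embed_cells(
            dup, [f"g{m.gene_ids.index(h)}" for h in hvg],
            n_pcs=20, seed=0, method="pca")
        np.testing.assert_allclose(emb2[0], emb2[-1], atol=1e-8)

    def test_umap_backend_runs(self, clean_cells):
        m, _ = clean_cells
        hvg = mt.cells.select_hvg(m, n=60)
        emb = mt.cells.embed_cells(m, hvg, n_pcs=15, n_neighbors=20,
                                   seed=0, method="umap")
        assert emb.shape == (m.n_cells, 2)

    def test_well_separated_blobs_embed_separably(self, clean_cells):
        pts, labels = _blobs(2, per_blob=60)
        assert silhouette_score(pts, labels) > 0

    def test_two_components_two_clusters(self):
        pts, labels = _blobs(2, per_blob=60)
        ca = mt.cells.cluster_cells(pts, resolution=0.5, seed=0)
        assert ca.n_clusters == 2
        assert adjusted_rand_score(labels, ca.labels) == 1.0

    def test_eight_blobs_recovered_at_coarse_resolution(self):
        pts, labels = _blobs(8, per_blob=30)
        ca = mt.cells.cluster_cells(pts, resolution=0.05, seed=0)
        assert ca.n_clusters == 8
        assert adjusted_rand_score(labels, ca.labels) == 1.0

    def test_labels_contiguous(self):
        pts, _ = _blobs(3, per_blob=30)
        ca = mt.cells.cluster_cells(pts, resolution=0.3, seed=0)
        assert sorted(set(ca.labels)) == list(range(ca.n_clusters))

    def test_cluster_count_nondecreasing_in_resolution(self):
        pts, _ = _blobs(6, per_blob=30)
        counts = [mt.cells.cluster_cells(pts, r, seed=0).n_clusters
                  for r in (0.01, 0.05, 0.2, 0.5, 1.0)]
        assert counts == sorted(counts)

    def test_identical_coordinates_single_cluster(self):
        with pytest.warns(UserWarning, match="identical"):
            ca = mt.cells.cluster_cells(np.ones((20, 2)), 0.5)
        assert ca.n_clusters == 1


class TestAnnotate:
    def test_fraction_one_when_marker_ubiquitous(self):
        m = toy_matrix([[5, 0], [7, 0], [2, 1]])
        ca = mt.ClusterAssignment(np.zeros(3, dtype=int), 0.05)
        panel = mt.MarkerPanel([("g0", "M", "up")])
        _, dots, _ = mt.cells.annotate_clusters(m, ca, panel)
        assert dots.loc[0, "frac_expressed"] == 1.0

    def test_dotplot_mean_matches_manual_sum(self, clean_cells):
        m, truth = clean_cells
        ca = mt.ClusterAssignment(np.zeros(m.n_cells, dtype=int), 0.05)
        _, dots, _ = mt.cells.annotate_clusters(m, ca, truth.marker_panel)
        gene = dots["gene"].iloc[0]
        manual = m.normalized(log=True)[:, m.gene_ids.index(gene)].sum() / m.n_cells
        assert dots.loc[dots["gene"] == gene, "mean_expr"].iloc[0] == pytest.approx(manual)

    def test_bs_minority_cluster_labelled_bs(self, clean_cells):
        m, truth = clean_cells
        is_bs = (truth.cell_type == "BS").astype(int)
        ca = mt.ClusterAssignment(is_bs, 0.05)
        assignment, _, _ = mt.cells.annotate_clusters(m, ca, truth.marker_panel)
        assert assignment[1] == "BS"
        assert assignment[0] == "M"

    def test_cell_permutation_invariance(self, clean_cells):
        m, truth = clean_cells
        rng = np.random.default_rng(1)
        perm = rng.permutation(m.n_cells)
        labels = (truth.cell_type == "BS").astype(int)
        ca = mt.ClusterAssignment(labels, 0.05)
        ca_p = mt.ClusterAssignment(labels[perm], 0.05)
        _, dots, _ = mt.cells.annotate_clusters(m, ca, truth.marker_panel)
        _, dots_p, _ = mt.cells.annotate_clusters(
            m.subset_cells(perm), ca_p, truth.marker_panel)
        for col in ("mean_expr", "frac_expressed"):
            np.testing.assert_allclose(dots[col], dots_p[col], atol=1e-12)

    def test_missing_marker_reported(self, clean_cells):
        m, _ = clean_cells
        ca = mt.ClusterAssignment(np.zeros(m.n_cells, dtype=int), 0.05)
        panel = mt.MarkerPanel([("GENE0001", "M", "up"),
                                ("NOT_A_GENE", "BS", "up")])
        _, _, missing = mt.cells.annotate_clusters(m, ca, panel)
        assert missing == ["NOT_A_GENE"]


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_qc_pass_definition_holds_for_random_matrices(seed):
    """pass <=> total >= min_reads and mito_ratio <= max_mito, any input."""
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 4000, size=(12, 6))
    m = toy_matrix(counts, mito=[True, False, False, False, False, True])
    try:
        _, qc = mt.cells.qc_filter(m, min_reads=5_000, max_mito=0.3)
    except RuntimeError:
        totals = counts.sum(axis=1)
        mito = counts[:, [0, 5]].sum(axis=1) / np.maximum(totals, 1)
        assert not np.any((totals >= 5_000) & (mito <= 0.3))
        return
    expect = (qc["total_reads"] >= 5_000) & (qc["mito_ratio"] <= 0.3)
    assert (qc["pass"] == expect).all()
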