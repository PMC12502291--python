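"""Normalization, HVG/DEG selection, gene-set algebra and scaling."""

import numpy as np
import pytest

from scgraphmap import preprocess as pp
from scgraphmap.data import ExpressionDataset, QUERY, REFERENCE
from scgraphmap.simdata import SimSpec, simulate_pair

from _oracles import degs_loop


def dataset(matrix, origin=REFERENCE, labels=None, **kw):
    matrix = np.asarray(matrix, dtype=float)
    return ExpressionDataset(
        matrix=matrix,
        cell_ids=np.array([f"c{i}" for i in range(matrix.shape[0])], dtype=object),
        gene_ids=np.array([f"g{j}" for j in range(matrix.shape[1])], dtype=object),
        origin=origin,
        labels=labels,
        **kw,
    )


class TestNormalizeLog:
    def test_equal_counts_rescale(self):
        ds = dataset([[2.0, 2.0], [1.0, 3.0]])
        out = pp.normalize_log(ds, target_sum=4, pseudocount=1)
        np.testing.assert_allclose(out.matrix[0], np.log(3.0))

    def test_zero_gene_column_stays_zero_with_unit_pseudocount(self):
        ds = dataset([[5.0, 0.0], [3.0, 0.0]])
        out = pp.normalize_log(ds, target_sum=10, pseudocount=1)
        np.testing.assert_allclose(out.matrix[:, 1], 0.0)

    def test_row_sums_reach_target_before_log(self):
        rng = np.random.default_rng(0)
        ds = dataset(rng.poisson(5, size=(3, 4)) + 1)
        out = pp.normalize_log(ds, target_sum=1e4, pseudocount=1)
        restored = np.exp(out.matrix) - 1.0
        np.testing.assert_allclose(restored.sum(axis=1), 1e4, atol=1e-4)

    def test_all_zero_cell_rejected_with_id(self):
        ds = dataset([[1.0, 1.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="c1"):
            pp.normalize_log(ds)

    def test_negative_entry_rejected_on_load(self):
        with pytest.raises(ValueError, match="negative"):
            dataset([[1.0, -1.0]])

    def test_labels_and_origin_preserved(self):
        ds = dataset([[1, 2], [3, 4]], labels=np.array(["a", "b"], dtype=object))
        out = pp.normalize_log(ds)
        assert out.origin == REFERENCE
        assert list(out.labels) == ["a", "b"]


class TestSelectHvgs:
    def test_small_panel_keeps_all_genes(self):
        rng = np.random.default_rng(1)
        ds = pp.normalize_log(dataset(rng.poisson(3, (30, 40)) + 1))
        assert pp.select_hvgs(ds, n_top=2000) == list(ds.gene_ids)

    def test_dominant_dispersion_gene_ranks_first(self):
        rng = np.random.default_rng(2)
        X = rng.poisson(5, size=(60, 10)).astype(float) + 1
        X[:30, 0] += 60  # one gene with far higher variance at similar mean rank
        ds = pp.normalize_log(dataset(X))
        top = pp.select_hvgs(ds, n_top=3)
        assert "g0" in top

    def test_matches_scanpy_dispersion_ranking(self):
        """The returned set equals an independent recomputation of the
        dispersion statistic used for the ranking."""
        import scanpy as sc

        rng = np.random.default_rng(3)
        ds = pp.normalize_log(dataset(rng.negative_binomial(2, 0.3, (80, 200)) + 1))
        got = set(pp.select_hvgs(ds, n_top=40))
        adata = ds.to_anndata()
        sc.pp.highly_variable_genes(adata, n_top_genes=40, flavor="seurat")
        expected = set(adata.var_names[adata.var["highly_variable"]])
        assert got == expected

    def test_requires_two_cells(self):
        ds = pp.normalize_log(dataset([[1.0, 2.0]]))
        with pytest.raises(ValueError):
            pp.select_hvgs(ds)


class TestPreclusterQuery:
    def test_two_blobs_recovered(self):
        rng = np.random.default_rng(4)
        a = rng.poisson(2, (50, 30)).astype(float)
        b = rng.poisson(2, (50, 30)).astype(float)
        a[:, :10] += rng.poisson(30, (50, 10))
        b[:, 20:] += rng.poisson(30, (50, 10))
        ds = pp.normalize_log(dataset(np.vstack([a, b]) + 1, origin=QUERY))
        labels = pp.precluster_query(ds, resolution=0.4, seed=0)
        assert len(set(labels)) == 2
        assert len(set(labels[:50])) == 1 and len(set(labels[50:])) == 1

    def test_identical_cells_give_single_cluster(self):
        ds = pp.normalize_log(
            dataset(np.tile([3.0, 1.0, 2.0, 5.0], (20, 1)), origin=QUERY)
        )
        labels = pp.precluster_query(ds, seed=0)
        assert len(set(labels)) == 1

    def test_deterministic_under_seed(self, small_sim):
        _, _, query, _ = small_sim
        ds = pp.normalize_log(query)
        first = pp.precluster_query(ds, seed=3)
        second = pp.precluster_query(ds, seed=3)
        assert list(first) == list(second)

    def test_rejects_reference(self):
        ds = pp.normalize_log(dataset([[1, 2], [3, 4]]))
        with pytest.raises(ValueError):
            pp.precluster_query(ds)


class TestRankDegs:
    def test_exclusive_gene_ranks_first(self):
        rng = np.random.default_rng(5)
        X = rng.poisson(2, size=(40, 20)).astype(float) + 1
        groups = np.array(["A"] * 20 + ["B"] * 20, dtype=object)
        X[:20, 7] += 50
        ds = pp.normalize_log(dataset(X))
        degs = pp.rank_degs(ds, groups)
        assert degs["A"][0] == "g7"

    def test_null_gene_excluded(self):
        rng = np.random.default_rng(6)
        X = np.ones((30, 5)) * 4  # identical across groups
        X += rng.normal(scale=1e-6, size=X.shape) ** 2
        groups = np.array(["A"] * 15 + ["B"] * 15, dtype=object)
        ds = dataset(X).with_matrix(np.log1p(X), "normalized")
        degs = pp.rank_degs(ds, groups)
        assert degs["A"] == [] and degs["B"] == []

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.poisson(3, size=(60, 100)).astype(float) + 1
        groups = np.array(list("ABC") * 20, dtype=object)
        for g, cols in zip("ABC", (range(5), range(5, 10), range(10, 15))):
            X[np.ix_(groups == g, list(cols))] += rng.poisson(8, (20, 5))
        ds = pp.normalize_log(dataset(X))
        got = pp.rank_degs(ds, groups, n_top=50)
        expected = degs_loop(ds.matrix, ds.gene_ids, groups, n_top=50)
        assert got == expected

    def test_singleton_group_rejected(self):
        ds = pp.normalize_log(dataset([[1, 2], [3, 4], [5, 6]]))
        with pytest.raises(ValueError, match="lonely"):
            pp.rank_degs(ds, np.array(["lonely", "x", "x"], dtype=object))


class TestBuildGeneSets:
    def _pair(self):
        rng = np.random.default_rng(8)
        ref = pp.normalize_log(dataset(rng.poisson(3, (10, 6)) + 1))
        qry = pp.normalize_log(dataset(rng.poisson(3, (10, 5)) + 1, origin=QUERY))
        qry.gene_ids = np.array(["g1", "g2", "g3", "g4", "gX"], dtype=object)
        return ref, qry

    def test_intersection_rule(self):
        ref, qry = self._pair()
        sel = pp.build_gene_sets(
            ref, qry, ["g0", "g1", "g2"], ["g1", "g2", "gX"], {}, {}
        )
        assert sel.node_genes == ["g1", "g2"]

    def test_disjoint_selection_errors_with_sizes(self):
        ref, qry = self._pair()
        with pytest.raises(ValueError, match="selected 2"):
            pp.build_gene_sets(ref, qry, ["g0", "g5"], ["gX"], {}, {})

    def test_symmetric_in_dataset_order(self):
        ref, qry = self._pair()
        a = pp.build_gene_sets(
            ref, qry, ["g1", "g3"], ["g1", "g2", "g3"], {"t": ["g2"]}, {"0": ["g4"]}
        )
        b = pp.build_gene_sets(
            ref, qry, ["g1", "g2", "g3"], ["g1", "g3"], {"0": ["g4"]}, {"t": ["g2"]}
        )
        assert set(a.node_genes) == set(b.node_genes)

    def test_generator_markers_in_node_and_feature_genes(self, small_sim):
        spec, ref, query, _ = small_sim
        ref_n, query_n = pp.normalize_log(ref), pp.normalize_log(query)
        hvgs_r = pp.select_hvgs(ref_n)
        hvgs_q = pp.select_hvgs(query_n)
        degs_r = pp.rank_degs(ref_n, ref_n.labels)
        sel = pp.build_gene_sets(ref_n, query_n, hvgs_r, hvgs_q, degs_r, {})
        shared = set(ref.gene_ids) & set(query.gene_ids)
        # panels <= 2000 genes keep everything, so node genes = shared panel
        assert set(sel.node_genes) == (set(hvgs_r) | set().union(*degs_r.values())) & set(hvgs_q) & shared
        markers = {g for genes in spec.marker_map().values() for g in genes}
        assert markers <= set(sel.node_genes)
        assert set(sel.feature_genes) == set().union(*degs_r.values()) & shared


class TestScaleFeatures:
    def test_column_moments(self):
        rng = np.random.default_rng(9)
        ds = pp.normalize_log(dataset(rng.poisson(4, (50, 20)) + 1))
        out = pp.scale_features(ds)
        assert np.abs(out.matrix.mean(axis=0)).max() < 1e-8
        np.testing.assert_allclose(out.matrix.var(axis=0), 1.0, atol=1e-6)

    def test_three_point_column(self):
        ds = dataset([[1.0], [2.0], [3.0]]).with_matrix(
            np.array([[1.0], [2.0], [3.0]]), "normalized"
        )
        out = pp.scale_features(ds)
        np.testing.assert_allclose(
            out.matrix.ravel(), [-1.22474487, 0.0, 1.22474487], atol=1e-8
        )

    def test_constant_column_maps_to_zero(self):
        ds = dataset([[5.0, 1.0], [5.0, 2.0]]).with_matrix(
            np.array([[5.0, 1.0], [5.0, 2.0]]), "normalized"
        )
        out = pp.scale_features(ds)
        np.testing.assert_allclose(out.matrix[:, 0], 0.0)

    def test_idempotent(self):
        rng = np.random.default_rng(10)
        ds = pp.normalize_log(dataset(rng.poisson(4, (30, 10)) + 1))
        once = pp.scale_features(ds)
        twice = pp.scale_features(once)
        np.testing.assert_allclose(once.matrix, twice.matrix, atol=1e-6)
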