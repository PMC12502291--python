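"""Unknown detection, gene modules, importance, similarity, metrics."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from scgraphmap.postanalysis import (
    UnknownConfig,
    celltype_distance,
    compute_metrics,
    detect_unknown,
    extract_gene_modules,
    gene_importance,
    gene_similarity,
    module_type_means,
)
from scgraphmap.trainer import PredictionResult

from _oracles import metrics_loop


def prediction(max_prob, labels, classes=("A", "B")):
    max_prob = np.asarray(max_prob, dtype=float)
    labels = np.asarray(labels, dtype=object)
    n, C = len(labels), len(classes)
    probs = np.full((n, C), (1 - max_prob)[:, None] / (C - 1))
    for i, lab in enumerate(labels):
        probs[i, list(classes).index(lab)] = max_prob[i]
    return PredictionResult(
        cell_ids=np.array([f"q{i}" for i in range(n)], dtype=object),
        classes=list(classes),
        probabilities=probs,
        labels=labels,
        max_prob=max_prob,
    )


class TestCelltypeDistance:
    def test_coincident_points_have_zero_distance(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(size=(30, 20))
        out = celltype_distance(
            ref[:10], np.array(["t"] * 10, dtype=object), ref,
            UnknownConfig(n_neighbors=1),
        )
        assert out["t"] == pytest.approx(0.0, abs=1e-9)

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(40, 10))
        query = rng.normal(size=(15, 10))
        types = np.array(["a"] * 7 + ["b"] * 8, dtype=object)
        cfg = UnknownConfig(pca_dim=10, n_neighbors=5)  # pca_dim = dim -> identity
        got = celltype_distance(query, types, ref, cfg)
        per_cell = np.empty(15)
        for i in range(15):
            d = np.sort(np.linalg.norm(ref - query[i], axis=1))
            per_cell[i] = d[:5].mean()
        assert got["a"] == pytest.approx(per_cell[:7].mean(), rel=1e-9)
        assert got["b"] == pytest.approx(per_cell[7:].mean(), rel=1e-9)

    def test_displaced_type_has_larger_distance(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(size=(50, 60))
        near = ref[:20] + rng.normal(scale=0.05, size=(20, 60))
        far = ref[:20] + 30.0
        types = np.array(["near"] * 20 + ["far"] * 20, dtype=object)
        out = celltype_distance(np.vstack([near, far]), types, ref)
        assert out["far"] > out["near"] * 5


class TestDetectUnknown:
    def test_equal_probabilities_flag_nothing(self):
        pred = prediction([0.6] * 8, ["A"] * 8)
        flags = detect_unknown(pred, {"A": 100.0})
        assert not flags.any()

    def test_conjunction_requires_both_rules(self):
        pred = prediction([0.9, 0.9, 0.2, 0.2], ["A", "B", "A", "B"])
        flags = detect_unknown(pred, {"A": 1.0, "B": 9.0}, UnknownConfig())
        # below-median cells: indices 2, 3; only B exceeds the threshold
        assert list(flags) == [False, False, False, True]

    def test_low_confidence_type_skips_distance_rule(self):
        pred = prediction([0.9, 0.2], ["A", "A"])
        cfg = UnknownConfig(low_confidence_types=["A"])
        flags = detect_unknown(pred, {"A": 0.1}, cfg)
        assert list(flags) == [False, True]

    def test_flags_subset_of_below_median(self):
        rng = np.random.default_rng(3)
        pred = prediction(rng.random(50), rng.choice(["A", "B"], 50))
        flags = detect_unknown(pred, {"A": 10.0, "B": 10.0})
        below = pred.max_prob < np.median(pred.max_prob)
        assert (flags <= below).all()


class TestGeneModules:
    def test_recovers_separated_blocks(self):
        rng = np.random.default_rng(4)
        emb = np.vstack([
            rng.normal(loc=center, scale=0.1, size=(20, 16))
            for center in (0.0, 8.0, -8.0)
        ])
        ids = [f"g{i}" for i in range(60)]
        modules = extract_gene_modules(emb, ids, seed=0)
        assert modules.n_modules == 3
        truth = np.repeat([0, 1, 2], 20)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, modules.module_ids) == 1.0

    def test_identical_embeddings_one_module(self):
        emb = np.ones((10, 4))
        modules = extract_gene_modules(emb, [f"g{i}" for i in range(10)], seed=0)
        assert modules.n_modules == 1

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        emb = rng.normal(size=(40, 8))
        a = extract_gene_modules(emb, [f"g{i}" for i in range(40)], seed=9)
        b = extract_gene_modules(emb, [f"g{i}" for i in range(40)], seed=9)
        np.testing.assert_array_equal(a.module_ids, b.module_ids)

    def test_module_type_means_table(self):
        emb = np.vstack([np.zeros((3, 4)), np.ones((3, 4)) * 9])
        ids = [f"g{i}" for i in range(6)]
        modules = extract_gene_modules(emb, ids, seed=0)
        expr = np.arange(12, dtype=float).reshape(2, 6)
        table = module_type_means(modules, expr, ids, np.array(["x", "y"], dtype=object))
        assert table.shape == (modules.n_modules, 2)
        m0 = modules.module_ids == 0
        assert table.loc[0, "x"] == pytest.approx(expr[0, m0].mean())


class TestGeneImportance:
    def test_single_cell_single_gene(self):
        att = sp.csr_matrix(np.array([[1.0, 0.0]]))
        out = gene_importance(att, np.array(["t"], dtype=object), ["g0", "g1"])
        assert out.loc["t", "g0"] == 1.0 and out.loc["t", "g1"] == 0.0

    def test_uniform_attention(self):
        att = sp.csr_matrix(np.full((3, 4), 0.25))
        out = gene_importance(att, np.array(["t"] * 3, dtype=object), list("abcd"))
        np.testing.assert_allclose(out.loc["t"], 0.25)

    def test_matches_loop_aggregation_and_convexity(self):
        rng = np.random.default_rng(6)
        dense = rng.random((10, 5)) * (rng.random((10, 5)) > 0.4)
        dense /= np.where(dense.sum(1, keepdims=True) == 0, 1, dense.sum(1, keepdims=True))
        types = rng.choice(["u", "v"], 10)
        out = gene_importance(sp.csr_matrix(dense), types, [f"g{j}" for j in range(5)])
        for t in ("u", "v"):
            for j in range(5):
                vals = [
                    dense[i, j]
                    for i in range(10)
                    if types[i] == t and dense[i, j] > 0
                ]
                expected = float(np.mean(vals)) if vals else 0.0
                assert out.loc[t, f"g{j}"] == pytest.approx(expected)
        assert ((out.values >= 0) & (out.values <= 1)).all()


class TestGeneSimilarity:
    def test_identical_orthogonal_and_random(self):
        emb = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 2.0], [3.0, 4.0]])
        ids = ["a", "b", "c", "d"]
        sims = gene_similarity(emb, ids, [("a", "b"), ("a", "c"), ("a", "d")])
        assert sims[0] == pytest.approx(1.0)
        assert sims[1] == pytest.approx(0.0)
        assert sims[2] == pytest.approx(3.0 / 5.0)

    def test_unknown_gene_rejected_by_name(self):
        with pytest.raises(KeyError, match="nope"):
            gene_similarity(np.eye(2), ["a", "b"], [("a", "nope")])


class TestComputeMetrics:
    def test_perfect_prediction(self):
        rep = compute_metrics(["A", "B", "A"], ["A", "B", "A"])
        assert rep.accuracy == rep.macro_f1 == rep.weighted_f1 == 1.0

    def test_hand_computed_example(self):
        rep = compute_metrics(["A", "A", "B"], ["A", "B", "B"])
        assert rep.accuracy == pytest.approx(2 / 3)
        assert rep.macro_f1 == pytest.approx(2 / 3)
        assert rep.weighted_f1 == pytest.approx(2 / 3)

    def test_matches_confusion_loop_oracle_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            t = rng.choice(list("ABCD"), 200)
            p = rng.choice(list("ABCD"), 200)
            rep = compute_metrics(t, p)
            acc, macro, weighted = metrics_loop(t, p)
            assert rep.accuracy == pytest.approx(acc, abs=1e-12)
            assert rep.macro_f1 == pytest.approx(macro, abs=1e-12)
            assert rep.weighted_f1 == pytest.approx(weighted, abs=1e-12)

    def test_accuracy_equals_weighted_recall(self):
        rng = np.random.default_rng(8)
        t = rng.choice(["x", "y", "z"], 150)
        p = rng.choice(["x", "y", "z"], 150)
        rep = compute_metrics(t, p)
        weighted_recall = sum(
            rep.per_class.loc[c, "recall"] * rep.per_class.loc[c, "support"]
            for c in rep.per_class.index
        ) / len(t)
        assert rep.accuracy == pytest.approx(weighted_recall)

    def test_macro_invariant_under_relabeling(self):
        rng = np.random.default_rng(9)
        t = rng.choice(list("AB"), 80)
        p = rng.choice(list("AB"), 80)
        swap = {"A": "B", "B": "A"}
        a = compute_metrics(t, p)
        b = compute_metrics([swap[x] for x in t], [swap[x] for x in p])
        assert a.macro_f1 == pytest.approx(b.macro_f1)

    def test_missing_predicted_class_scores_zero(self):
        rep = compute_metrics(["A", "A", "B", "B"], ["A", "A", "A", "A"])
        assert rep.per_class.loc["B", "f1"] == 0.0
        assert rep.macro_f1 == pytest.approx(rep.per_class.loc["A", "f1"] / 2)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([], [])
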