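"""Labeled sets, the five scorers, AUROC, and cross-validation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from atrokg.kg import KnowledgeGraph
from atrokg.linkpred import (
    CVConfig,
    LabeledEdgeSet,
    LinkScorer,
    auroc,
    cross_validate,
    make_labeled_set,
    roc_points,
    sample_negatives,
    score_preferential_attachment,
    train_gb,
    train_mlp,
    train_rf,
)

from conftest import random_bipartite


def brute_force_auroc(scores, labels) -> float:
    """Concordant-pair count over all positive-negative pairs, ties = 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_separation_gives_one(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_known_small_example(self):
        # positives 0.9, 0.7; negatives 0.8, 0.3: 3 of 4 concordant
        assert auroc([0.9, 0.8, 0.7, 0.3], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        assert auroc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == pytest.approx(0.5)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(10, 200))
            scores = rng.choice(np.round(rng.random(12), 2), size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            assert auroc(scores, labels) == pytest.approx(
                brute_force_auroc(scores, labels), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])

    def test_roc_points_monotone(self):
        pts = roc_points([0.9, 0.8, 0.4, 0.2], [1, 0, 1, 0])
        assert (pts["fpr"].diff().dropna() >= 0).all()
        assert (pts["tpr"].diff().dropna() >= 0).all()


class TestLabeledSets:
    @pytest.fixture(scope="class")
    def kg(self):
        return random_bipartite(12, 10, 0.35, seed=5)

    def test_split_counts_follow_train_fraction(self, kg):
        train, test = make_labeled_set(kg, train_fraction=0.8, seed=0)
        n_edges = kg.n_edges
        assert len(train.positives) == int(round(0.8 * n_edges))
        assert len(test.positives) == n_edges - len(train.positives)
        # 1:1 negatives per split
        assert len(train.negatives) == len(train.positives)
        assert len(test.negatives) == len(test.positives)

    def test_ddkg_style_sixty_forty_split(self, kg):
        train, test = make_labeled_set(kg, train_fraction=0.6, seed=1)
        assert len(train.positives) == int(round(0.6 * kg.n_edges))

    def test_negatives_are_genuine_non_edges_and_disjoint(self, kg):
        train, test = make_labeled_set(kg, train_fraction=0.7, seed=2)
        for u, v in train.negatives + test.negatives:
            assert not kg.has_edge(u, v)
        assert set(train.negatives).isdisjoint(test.negatives)
        assert set(train.pairs).isdisjoint(test.pairs)

    def test_sample_negatives_never_returns_edges(self, kg):
        negs = sample_negatives(kg, 30, seed=3)
        assert len(negs) == len(set(negs)) == 30
        for u, v in negs:
            assert not kg.has_edge(u, v)
            assert kg.node_type(u) != kg.node_type(v)


def _separable_problem(n=120, seed=0):
    """Toy: feature sign determines the label; linearly separable."""
    rng = np.random.default_rng(seed)
    names = [f"n{i:03d}" for i in range(n)]
    labels = rng.integers(0, 2, size=n // 2)
    pairs = [(names[2 * i], names[2 * i + 1]) for i in range(n // 2)]
    feats = np.zeros((n, 4))
    for i, y in enumerate(labels):
        val = 1.0 if y else -1.0
        feats[2 * i] = val + 0.01 * rng.standard_normal(4)
        feats[2 * i + 1] = val + 0.01 * rng.standard_normal(4)
    table = pd.DataFrame(feats, index=names)
    return LabeledEdgeSet(pairs, labels), table


class TestTreeScorers:
    def test_rf_fits_separable_toy_perfectly(self):
        train, table = _separable_problem(seed=1)
        scorer = train_rf(train, table, n_estimators=50, seed=0)
        assert auroc(scorer.score_pairs(train.pairs), train.labels) == 1.0

    def test_gb_fits_separable_toy_perfectly(self):
        train, table = _separable_problem(seed=2)
        scorer = train_gb(train, table, n_estimators=50, seed=0)
        assert auroc(scorer.score_pairs(train.pairs), train.labels) == 1.0

    def test_gb_scores_monotone_in_single_informative_feature(self):
        rng = np.random.default_rng(3)
        n = 60
        names = [f"n{i:03d}" for i in range(2 * n)]
        x = np.sort(rng.uniform(-2, 2, size=n))
        labels = (x > 0).astype(int)  # monotone in the single feature
        feats = np.zeros((2 * n, 1))
        feats[::2, 0] = x
        feats[1::2, 0] = x
        table = pd.DataFrame(feats, index=names)
        pairs = [(names[2 * i], names[2 * i + 1]) for i in range(n)]
        # mean combiner keeps the edge feature equal to x (hadamard would square it)
        scorer = train_gb(LabeledEdgeSet(pairs, labels), table, combiner="mean", seed=0)
        scores = scorer.score_pairs(pairs)
        # scores ordered like the feature (allowing flat stretches)
        assert np.all(np.diff(scores) >= -1e-9)

    def test_single_class_labels_rejected(self):
        train, table = _separable_problem(seed=4)
        bad = LabeledEdgeSet(train.pairs, np.ones(len(train.pairs), int))
        with pytest.raises(ValueError):
            train_rf(bad, table)


class TestMlpScorer:
    def test_xor_structure_is_learnable(self):
        rng = np.random.default_rng(5)
        n = 80
        names = [f"n{i:03d}" for i in range(2 * n)]
        a = rng.choice([-1.0, 1.0], size=n)
        b = rng.choice([-1.0, 1.0], size=n)
        labels = ((a * b) > 0).astype(int)  # XOR-style parity of the two coords
        feats = np.zeros((2 * n, 2))
        feats[::2] = np.c_[a, b] + 0.05 * rng.standard_normal((n, 2))
        feats[1::2] = np.c_[a, b] + 0.05 * rng.standard_normal((n, 2))
        table = pd.DataFrame(feats, index=names)
        pairs = [(names[2 * i], names[2 * i + 1]) for i in range(n)]
        scorer = train_mlp(
            LabeledEdgeSet(pairs, labels),
            table,
            hidden_layer_sizes=(32, 32),
            max_iter=500,
            seed=0,
        )
        acc = ((scorer.score_pairs(pairs) > 0.5).astype(int) == labels).mean()
        assert acc > 0.95

    def test_missing_embedding_is_named(self):
        train, table = _separable_problem(seed=6)
        with pytest.raises(KeyError, match="n000"):
            train_mlp(train, table.drop(index="n000"))

    def test_same_seed_identical_predictions(self):
        train, table = _separable_problem(seed=7)
        s1 = train_mlp(train, table, hidden_layer_sizes=(8,), seed=3)
        s2 = train_mlp(train, table, hidden_layer_sizes=(8,), seed=3)
        np.testing.assert_array_equal(s1.score_pairs(train.pairs), s2.score_pairs(train.pairs))


class TestPreferentialAttachmentScorer:
    def test_ordering_matches_neighbor_count_product(self):
        kg = random_bipartite(10, 8, 0.3, seed=9)
        genes, diseases = kg.nodes_of_type("gene"), kg.nodes_of_type("disease")
        pairs = [(g, d) for g in genes[:5] for d in diseases[:5]]
        scores = score_preferential_attachment(kg, pairs)
        expected = [kg.degree(u) * kg.degree(v) for u, v in pairs]
        assert np.argsort(scores).tolist() == np.argsort(expected, kind="stable").tolist() or (
            np.allclose(scores, expected)
        )

    def test_minmax_scaling_preserves_auroc(self):
        kg = random_bipartite(10, 8, 0.3, seed=10)
        train, test = make_labeled_set(kg, train_fraction=0.7, seed=0)
        raw = score_preferential_attachment(kg, test.pairs)
        scaled = score_preferential_attachment(kg, test.pairs, scaled=True)
        assert np.all(scaled >= 0) and np.all(scaled <= 1)
        assert auroc(raw, test.labels) == pytest.approx(auroc(scaled, test.labels))

    def test_all_isolated_pairs_score_zero_auroc_half(self):
        kg = random_bipartite(4, 3, 0.5, seed=11)
        for v in ["x1", "x2", "x3", "x4"]:
            kg.graph.add_node(v, ntype="gene")
        pairs = [("x1", "x2"), ("x3", "x4")]
        scores = score_preferential_attachment(kg, pairs)
        assert np.all(scores == 0)
        assert auroc(scores, [1, 0]) == pytest.approx(0.5)


class TestCrossValidate:
    @pytest.fixture(scope="class")
    def kg(self):
        return random_bipartite(15, 12, 0.3, seed=13)

    def test_report_has_k_fold_entries(self, kg):
        rep = cross_validate("preferential_attachment", kg, k=5, seed=0)
        assert len(rep.fold_aurocs) == 5
        assert rep.auroc == pytest.approx(np.mean(rep.fold_aurocs))

    def test_label_peeking_oracle_scores_every_fold_perfectly(self, kg):
        """Upper-bound harness check: an oracle that looks up the full graph's
        edges must get AUROC 1.0 in every fold."""
        full_edges = set(kg.edges())

        def oracle(train_graph, train, seed):
            return LinkScorer(
                method="oracle",
                _score_fn=lambda pairs: [
                    1.0 if tuple(sorted(p)) in full_edges else 0.0 for p in pairs
                ],
            )

        rep = cross_validate(oracle, kg, k=4, seed=1)
        assert rep.fold_aurocs == [1.0] * 4

    def test_default_fold_count_is_ten(self, kg):
        import inspect

        assert inspect.signature(cross_validate).parameters["k"].default == 10

    def test_rf_cross_validation_runs_and_reports(self, kg):
        rep = cross_validate("rf", kg, k=3, seed=2, config=CVConfig(rf_estimators=30))
        assert len(rep.fold_aurocs) == 3
        assert all(0.0 <= a <= 1.0 for a in rep.fold_aurocs)
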