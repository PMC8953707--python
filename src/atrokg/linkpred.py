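"""Link prediction on typed knowledge graphs.

Labeled-set construction (edge holdout + uniform negative sampling over
cross-type non-edges), four trainable scorers — random forest and gradient
boosting on node-centrality edge features, a deep MLP on random-walk
embedding features, and a two-layer graph convolutional network — plus the
preferential-attachment baseline, rank-based AUROC and k-fold
cross-validation with per-fold negative resampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .embeddings import embed_nodes
from .features import edge_feature_matrix, generate_walks, node_feature_table, preferential_attachment
from .gcn import GCN, GCNConfig
from .kg import KnowledgeGraph

logger = logging.getLogger(__name__)

METHODS = ("rf", "gb", "mlp", "gcn", "preferential_attachment")

Pair = tuple[str, str]


def _canon(u: str, v: str) -> Pair:
    return (u, v) if u <= v else (v, u)


@dataclass
class LabeledEdgeSet:
    """Node pairs labeled 1 (existent edge) / 0 (sampled non-edge)."""

    pairs: list[Pair]
    labels: np.ndarray
    tag: str = ""
    negative_ratio: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.pairs = [_canon(u, v) for u, v in self.pairs]
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.pairs) != len(self.labels):
            raise ValueError("labels and pairs length mismatch")

    @property
    def positives(self) -> list[Pair]:
        return [p for p, y in zip(self.pairs, self.labels) if y == 1]

    @property
    def negatives(self) -> list[Pair]:
        return [p for p, y in zip(self.pairs, self.labels) if y == 0]

    def __len__(self) -> int:
        return len(self.pairs)


def sample_negatives(
    kg: KnowledgeGraph,
    n: int,
    seed: int,
    exclude: Iterable[Pair] = (),
    type_pair: tuple[str, str] | None = None,
) -> list[Pair]:
    """Sample ``n`` distinct cross-type non-edges uniformly at random.

    Candidates are pairs whose types match an edge type-pair of the graph
    (same-type pairs are never candidates, keeping the bipartite task
    well-posed).  ``exclude`` pairs (e.g. held-out positives) are avoided.
    """
    rng = np.random.default_rng(seed)
    if type_pair is None:
        type_pairs = sorted({tuple(sorted((kg.node_type(u), kg.node_type(v)))) for u, v in kg.edges()})
        if len(type_pairs) != 1:
            raise ValueError(f"ambiguous candidate type pair {type_pairs}; pass type_pair")
        type_pair = type_pairs[0]  # type: ignore[assignment]
    left = kg.nodes_of_type(type_pair[0])
    right = kg.nodes_of_type(type_pair[1])
    n_possible = len(left) * len(right) - kg.n_edges - len(set(exclude))
    if n > n_possible:
        raise ValueError(f"cannot sample {n} negatives; only {n_possible} non-edges available")
    forbidden = {_canon(u, v) for u, v in kg.edges()} | {_canon(u, v) for u, v in exclude}
    out: set[Pair] = set()
    while len(out) < n:
        us = rng.choice(left, size=n)
        vs = rng.choice(right, size=n)
        for u, v in zip(us, vs):
            p = _canon(str(u), str(v))
            if p not in forbidden and p not in out:
                out.add(p)
                if len(out) == n:
                    break
    return sorted(out)


def make_labeled_set(
    kg: KnowledgeGraph,
    train_fraction: float = 0.8,
    negative_ratio: float = 1.0,
    seed: int = 0,
) -> tuple[LabeledEdgeSet, LabeledEdgeSet]:
    """Split edges into train/test positives and attach sampled negatives.

    Negatives are drawn 1:``negative_ratio`` per split, are genuine non-edges
    of the *full* graph, and the two splits' negatives are disjoint.  Graph
    scorers must be fitted on the graph with test positives removed (use
    :meth:`KnowledgeGraph.subgraph_without_edges`).
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0,1)")
    rng = np.random.default_rng(seed)
    edges = kg.edges()
    order = rng.permutation(len(edges))
    n_train = int(round(train_fraction * len(edges)))
    train_pos = sorted(edges[i] for i in order[:n_train])
    test_pos = sorted(edges[i] for i in order[n_train:])
    n_train_neg = int(round(negative_ratio * len(train_pos)))
    n_test_neg = int(round(negative_ratio * len(test_pos)))
    negs = sample_negatives(kg, n_train_neg + n_test_neg, seed=seed + 1)
    negs = list(np.random.default_rng(seed + 2).permutation(negs))
    train_neg = sorted(map(tuple, negs[:n_train_neg]))
    test_neg = sorted(map(tuple, negs[n_train_neg:]))
    train = LabeledEdgeSet(
        train_pos + train_neg,
        np.r_[np.ones(len(train_pos), int), np.zeros(len(train_neg), int)],
        tag="train",
        negative_ratio=negative_ratio,
        seed=seed,
    )
    test = LabeledEdgeSet(
        test_pos + test_neg,
        np.r_[np.ones(len(test_pos), int), np.zeros(len(test_neg), int)],
        tag="test",
        negative_ratio=negative_ratio,
        seed=seed,
    )
    return train, test


# ---------------------------------------------------------------------------
# Scorers
# ---------------------------------------------------------------------------

@dataclass
class LinkScorer:
    """Fitted link scorer: maps node pairs to scores (probabilities for the
    learned methods, raw products for preferential attachment)."""

    method: str
    _score_fn: object = field(repr=False)

    def score_pairs(self, pairs: Sequence[Pair]) -> np.ndarray:
        return np.asarray(self._score_fn(pairs), dtype=float)


def _sklearn_scorer(method: str, model, table: pd.DataFrame, combiner: str) -> LinkScorer:
    def fn(pairs):
        x = edge_feature_matrix(table, pairs, combiner)
        return model.predict_proba(x)[:, 1]

    return LinkScorer(method=method, _score_fn=fn)


def _check_labels(train: LabeledEdgeSet) -> None:
    if len(set(train.labels.tolist())) < 2:
        raise ValueError("training labels contain a single class")


def train_rf(
    train: LabeledEdgeSet,
    features: pd.DataFrame,
    combiner: str = "mean",
    n_estimators: int = 500,
    max_depth: int = 15,
    seed: int = 0,
) -> LinkScorer:
    """Random forest on per-edge feature vectors (500 trees, depth <= 15)."""
    _check_labels(train)
    x = edge_feature_matrix(features, train.pairs, combiner)
    model = RandomForestClassifier(
        n_estimators=n_estimators, max_depth=max_depth, random_state=seed, n_jobs=1
    )
    model.fit(x, train.labels)
    return _sklearn_scorer("rf", model, features, combiner)


def train_gb(
    train: LabeledEdgeSet,
    features: pd.DataFrame,
    combiner: str = "mean",
    learning_rate: float = 0.2,
    n_estimators: int = 100,
    seed: int = 0,
) -> LinkScorer:
    """Stage-wise gradient-boosted trees, learning rate 0.2."""
    _check_labels(train)
    x = edge_feature_matrix(features, train.pairs, combiner)
    model = GradientBoostingClassifier(
        learning_rate=learning_rate, n_estimators=n_estimators, random_state=seed
    )
    model.fit(x, train.labels)
    return _sklearn_scorer("gb", model, features, combiner)


def train_mlp(
    train: LabeledEdgeSet,
    embeddings: pd.DataFrame,
    combiner: str = "mean",
    hidden_layer_sizes: tuple[int, ...] = (100,) * 10,
    solver: str = "lbfgs",
    max_iter: int = 200,
    seed: int = 0,
) -> LinkScorer:
    """Deep MLP (ten ReLU hidden layers of 100 units, L-BFGS solver) on
    random-walk embedding edge features."""
    _check_labels(train)
    missing = sorted({n for p in train.pairs for n in p} - set(embeddings.index))
    if missing:
        raise KeyError(f"no embedding for nodes: {missing}")
    x = edge_feature_matrix(embeddings, train.pairs, combiner)
    # standardized inputs keep the deep ReLU stack in lbfgs's working range
    model = make_pipeline(
        StandardScaler(),
        MLPClassifier(
            hidden_layer_sizes=hidden_layer_sizes,
            activation="relu",
            solver=solver,
            max_iter=max_iter,
            random_state=seed,
        ),
    )
    model.fit(x, train.labels)
    return _sklearn_scorer("mlp", model, embeddings, combiner)


def train_gcn(
    train_graph: KnowledgeGraph,
    train: LabeledEdgeSet,
    config: GCNConfig | None = None,
) -> LinkScorer:
    """Two-layer GCN encoder + inner-product/logistic decoder.

    ``train_graph`` must already have test positives removed so no label
    information leaks through the normalized adjacency.
    """
    _check_labels(train)
    model = GCN(config or GCNConfig())
    model.fit(train_graph, train.pairs, train.labels)
    return LinkScorer(method="gcn", _score_fn=model.score_pairs)


def score_preferential_attachment(
    kg: KnowledgeGraph, pairs: Sequence[Pair], scaled: bool = False
) -> np.ndarray:
    """Preferential-attachment scores |Gamma(u)||Gamma(v)| for node pairs.

    Only the ordering matters for AUROC; ``scaled=True`` min-max rescales to
    [0, 1] for probability-style reporting.
    """
    scores = np.array([preferential_attachment(kg, u, v) for u, v in pairs], dtype=float)
    if scaled and len(scores):
        lo, hi = scores.min(), scores.max()
        scores = np.zeros_like(scores) if hi == lo else (scores - lo) / (hi - lo)
    return scores


def pa_scorer(kg: KnowledgeGraph) -> LinkScorer:
    return LinkScorer(
        method="preferential_attachment",
        _score_fn=lambda pairs: score_preferential_attachment(kg, pairs),
    )


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve, rank (Mann-Whitney) formulation.

    Equals the probability that a uniformly chosen positive outranks a
    uniformly chosen negative, ties counting one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC requires both classes")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_points(scores: Sequence[float], labels: Sequence[int]) -> pd.DataFrame:
    """ROC curve points (fpr, tpr, threshold) for plotting."""
    fpr, tpr, thr = roc_curve(np.asarray(labels, int), np.asarray(scores, float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


@dataclass
class CVConfig:
    """Hyperparameters shared by cross-validation and the pipeline.

    Walk/embedding settings intentionally default to small values adequate
    for the graph sizes this package targets; the classic feature-learning
    defaults (10 walks of length 80, window 10, dimension 128) remain
    available by overriding fields.
    """

    negative_ratio: float = 1.0
    combiner: str = "mean"
    # random-walk embedding settings (mlp input)
    walks_per_node: int = 4
    walk_length: int = 30
    p: float = 1.0
    q: float = 1.0
    dim: int = 64
    window: int = 5
    epochs: int = 3
    # learner settings
    rf_estimators: int = 500
    rf_depth: int = 15
    gb_learning_rate: float = 0.2
    gb_estimators: int = 100
    mlp_hidden: tuple[int, ...] = (100,) * 10
    mlp_max_iter: int = 200
    gcn: GCNConfig = field(default_factory=GCNConfig)


def _fit_scorer(
    method: str,
    train_graph: KnowledgeGraph,
    train: LabeledEdgeSet,
    config: CVConfig,
    seed: int,
) -> LinkScorer:
    """Fit one scorer with all graph-derived inputs computed on train_graph."""
    if callable(method):  # custom factory: (train_graph, train, seed) -> LinkScorer
        return method(train_graph, train, seed)
    if method == "rf":
        feats = node_feature_table(train_graph)
        return train_rf(train, feats, config.combiner, config.rf_estimators, config.rf_depth, seed)
    if method == "gb":
        feats = node_feature_table(train_graph)
        return train_gb(
            train, feats, config.combiner, config.gb_learning_rate, config.gb_estimators, seed
        )
    if method == "mlp":
        corpus = generate_walks(
            train_graph,
            p=config.p,
            q=config.q,
            walk_length=config.walk_length,
            walks_per_node=config.walks_per_node,
            seed=seed,
        )
        emb = embed_nodes(
            corpus, dim=config.dim, window=config.window, epochs=config.epochs, seed=seed
        )
        return train_mlp(
            train,
            emb,
            config.combiner,
            config.mlp_hidden,
            max_iter=config.mlp_max_iter,
            seed=seed,
        )
    if method == "gcn":
        return train_gcn(train_graph, train, replace(config.gcn, seed=seed))
    if method == "preferential_attachment":
        return pa_scorer(train_graph)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def fit_scorer(
    method: str,
    train_graph: KnowledgeGraph,
    train: LabeledEdgeSet,
    config: CVConfig | None = None,
    seed: int = 0,
) -> LinkScorer:
    return _fit_scorer(method, train_graph, train, config or CVConfig(), seed)


@dataclass
class CVReport:
    """Per-fold AUROC values and their mean (the aggregate convention)."""

    method: str
    fold_aurocs: list[float]
    seed: int
    aggregate: str = "mean_of_folds"

    @property
    def auroc(self) -> float:
        return float(np.mean(self.fold_aurocs))

    def to_row(self) -> dict:
        row = {"method": self.method}
        row.update({f"fold_{i + 1}": v for i, v in enumerate(self.fold_aurocs)})
        row["AUROC"] = self.auroc
        return row


def cross_validate(
    method: str,
    kg: KnowledgeGraph,
    k: int = 10,
    seed: int = 0,
    config: CVConfig | None = None,
) -> CVReport:
    """k-fold edge cross-validation of one link-prediction method.

    Edges are partitioned into k folds; each fold's positives are withheld
    (also from the message-passing graph), matched negatives are resampled
    with the fold seed, the scorer is fitted on the remainder and evaluated
    by AUROC on the withheld pairs.
    """
    config = config or CVConfig()
    if k < 2:
        raise ValueError("k must be >= 2")
    edges = kg.edges()
    if len(edges) < k:
        raise ValueError("fewer edges than folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(edges))
    folds = np.array_split(order, k)
    fold_aurocs = []
    for i, fold_idx in enumerate(folds):
        fold_seed = seed + 1000 * (i + 1)
        fold_set = set(fold_idx.tolist())
        test_pos = sorted(edges[j] for j in fold_idx)
        train_pos = sorted(edges[j] for j in order if j not in fold_set)
        train_graph = kg.subgraph_without_edges(test_pos)
        n_train_neg = int(round(config.negative_ratio * len(train_pos)))
        n_test_neg = int(round(config.negative_ratio * len(test_pos)))
        negs = sample_negatives(kg, n_train_neg + n_test_neg, seed=fold_seed)
        negs = list(np.random.default_rng(fold_seed + 1).permutation(negs))
        train_neg = sorted(map(tuple, negs[:n_train_neg]))
        test_neg = sorted(map(tuple, negs[n_train_neg:]))
        train = LabeledEdgeSet(
            train_pos + train_neg,
            np.r_[np.ones(len(train_pos), int), np.zeros(len(train_neg), int)],
            tag=f"fold{i}-train",
            seed=fold_seed,
        )
        scorer = _fit_scorer(method, train_graph, train, config, fold_seed)
        pairs = test_pos + test_neg
        labels = np.r_[np.ones(len(test_pos), int), np.zeros(len(test_neg), int)]
        fold_aurocs.append(auroc(scorer.score_pairs(pairs), labels))
    name = method if isinstance(method, str) else getattr(method, "__name__", "custom")
    return CVReport(method=name, fold_aurocs=fold_aurocs, seed=seed)
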