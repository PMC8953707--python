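"""Two-layer graph convolutional encoder with an inner-product link decoder.

The encoder follows the layer-wise propagation rule
``H(l+1) = sigma(A_hat H(l) W(l))`` with ``A_hat`` the symmetric self-looped
normalized adjacency.  Input features are one-hot node identities augmented
with a node-type indicator, so the model is structure-driven.  A pair (u, v)
is scored by the logistic squashing of the inner product of the two 16-d
output embeddings; training minimises binary cross-entropy over labeled
pairs with full-batch Adam.  All randomness flows from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp

from .features import normalized_adjacency
from .kg import NODE_TYPES, KnowledgeGraph


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def _rank_auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Tie-aware rank AUROC used for internal checkpoint selection."""
    from scipy.stats import rankdata

    labels = np.asarray(labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        return 0.5
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def propagate(
    a_hat: sp.spmatrix | np.ndarray,
    h: np.ndarray,
    w: np.ndarray,
    activation: Callable[[np.ndarray], np.ndarray] | None = relu,
) -> np.ndarray:
    """One graph-convolution layer: ``sigma(A_hat @ H @ W)``."""
    z = a_hat @ (h @ w)
    return z if activation is None else activation(z)


@dataclass
class GCNConfig:
    hidden1: int = 32
    hidden2: int = 16
    epochs: int = 2000
    learning_rate: float = 0.03
    # L2 penalty: the value giving the best internal-validation AUROC is
    # kept (graph size determines how much regularisation the identity
    # features need, so a single fixed value cannot serve all graphs)
    weight_decay_grid: tuple[float, ...] = (1e-4, 1e-3, 1e-2)
    # fraction of labeled pairs held out for checkpoint/decay selection; the
    # kept model is the one with the best validation AUROC, evaluated every
    # eval_every epochs (0 disables selection and keeps the last epoch of
    # the first grid value)
    validation_fraction: float = 0.1
    eval_every: int = 50
    seed: int = 0


class _Adam:
    def __init__(self, shapes, lr):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class GCN:
    """Semi-supervised link predictor over one knowledge graph.

    ``fit`` consumes the training graph (held-out test positives must
    already be removed so they cannot leak through ``A_hat``) and a labeled
    pair set; ``score_pairs`` returns probabilities in [0, 1].
    """

    def __init__(self, config: GCNConfig | None = None):
        self.config = config or GCNConfig()
        self.nodes_: list[str] | None = None
        self.embeddings_: np.ndarray | None = None
        self.losses_: list[float] = []
        self.weight_decay_: float | None = None

    # X = [I_N | type one-hot]; the first-layer product X @ W0 splits into a
    # per-node part W_id and a per-type part T @ W_type.
    def fit(self, kg: KnowledgeGraph, pairs: Sequence[tuple[str, str]], labels) -> "GCN":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        nodes = kg.node_order()
        self.nodes_ = nodes
        index = {v: i for i, v in enumerate(nodes)}
        n = len(nodes)
        t_onehot = np.zeros((n, len(NODE_TYPES)))
        for i, v in enumerate(nodes):
            t_onehot[i, NODE_TYPES.index(kg.node_type(v))] = 1.0

        pairs = list(pairs)
        iu_all = np.array([index[u] for u, _ in pairs], dtype=int)
        iv_all = np.array([index[v] for _, v in pairs], dtype=int)
        y_all = np.asarray(labels, dtype=float)

        # internal validation split shared by checkpoint and decay selection
        n_val = int(round(cfg.validation_fraction * len(y_all)))
        order = rng.permutation(len(y_all))
        val_idx, tr_idx = order[:n_val], order[n_val:]
        if n_val > 0 and (
            y_all[val_idx].sum() in (0, n_val) or y_all[tr_idx].sum() in (0, len(tr_idx))
        ):
            n_val, val_idx, tr_idx = 0, order[:0], order  # degenerate split: train on all
        # validation positives must not leak through the adjacency: a model
        # memorising the message graph would otherwise win checkpoint selection
        val_pos = [pairs[i] for i in val_idx if y_all[i] == 1]
        msg_graph = kg.subgraph_without_edges(val_pos) if val_pos else kg
        s, _ = normalized_adjacency(msg_graph)
        init_seed = int(rng.integers(2**31 - 1))

        grid = cfg.weight_decay_grid if n_val > 0 else cfg.weight_decay_grid[:1]
        best_val, best_emb, best_wd, best_losses = -np.inf, None, grid[0], []
        for wd in grid:
            val, emb, losses = self._train_once(
                s, t_onehot, iu_all, iv_all, y_all, tr_idx, val_idx, wd, init_seed
            )
            if val > best_val or best_emb is None:
                best_val, best_emb, best_wd, best_losses = val, emb, wd, losses
        self.embeddings_ = best_emb
        self.weight_decay_ = best_wd
        self.losses_ = best_losses
        self._index = index
        return self

    def _train_once(self, s, t_onehot, iu_all, iv_all, y_all, tr_idx, val_idx, wd, seed):
        cfg = self.config
        rng = np.random.default_rng(seed)
        n = t_onehot.shape[0]
        h1, h2 = cfg.hidden1, cfg.hidden2
        w_id = rng.normal(0.0, np.sqrt(2.0 / (n + h1)), size=(n, h1))
        w_type = rng.normal(0.0, np.sqrt(2.0 / (3 + h1)), size=(3, h1))
        w1 = rng.normal(0.0, np.sqrt(2.0 / (h1 + h2)), size=(h1, h2))
        iu, iv, y = iu_all[tr_idx], iv_all[tr_idx], y_all[tr_idx]
        b = len(y)
        n_val = len(val_idx)

        opt = _Adam([w_id.shape, w_type.shape, w1.shape], cfg.learning_rate)
        losses: list[float] = []
        val_history: list[float] = []
        best_val, best_emb = -np.inf, None
        for epoch in range(1, cfg.epochs + 1):
            z0 = w_id + t_onehot @ w_type  # == X @ W0
            sz0 = s @ z0
            hid = relu(sz0)
            emb = s @ (hid @ w1)  # linear output embeddings

            logits = np.einsum("bd,bd->b", emb[iu], emb[iv])
            prob = sigmoid(logits)
            eps = 1e-12
            loss = -np.mean(y * np.log(prob + eps) + (1 - y) * np.log(1 - prob + eps))
            losses.append(float(loss))

            g = (prob - y) / b  # dL/dlogit
            d_emb = np.zeros_like(emb)
            np.add.at(d_emb, iu, g[:, None] * emb[iv])
            np.add.at(d_emb, iv, g[:, None] * emb[iu])
            d_m1 = s @ d_emb  # S symmetric
            d_w1 = hid.T @ d_m1 + wd * w1
            d_hid = (d_m1 @ w1.T) * (sz0 > 0)
            d_z0 = s @ d_hid
            d_w_id = d_z0 + wd * w_id
            d_w_type = t_onehot.T @ d_z0 + wd * w_type
            opt.step([w_id, w_type, w1], [d_w_id, d_w_type, d_w1])

            if n_val > 0 and (epoch % cfg.eval_every == 0 or epoch == cfg.epochs):
                z0 = w_id + t_onehot @ w_type
                emb_now = s @ (relu(s @ z0) @ w1)
                val_scores = np.einsum(
                    "bd,bd->b", emb_now[iu_all[val_idx]], emb_now[iv_all[val_idx]]
                )
                val_auc = _rank_auroc(val_scores, y_all[val_idx])
                val_history.append(val_auc)
                if val_auc > best_val:
                    best_val, best_emb = val_auc, emb_now

        if best_emb is None:
            z0 = w_id + t_onehot @ w_type
            best_emb = s @ (relu(s @ z0) @ w1)
        # a run's quality is the mean validation AUROC over the second half of
        # training: steadier than any single checkpoint on small val sets
        run_score = (
            float(np.mean(val_history[len(val_history) // 2 :])) if val_history else -np.inf
        )
        return run_score, best_emb, losses

    def score_pairs(self, pairs: Sequence[tuple[str, str]]) -> np.ndarray:
        if self.embeddings_ is None:
            raise RuntimeError("GCN is not fitted")
        missing = sorted({x for p in pairs for x in p} - set(self._index))
        if missing:
            raise KeyError(f"nodes unknown to the fitted GCN: {missing}")
        iu = np.array([self._index[u] for u, _ in pairs], dtype=int)
        iv = np.array([self._index[v] for _, v in pairs], dtype=int)
        return sigmoid(np.einsum("bd,bd->b", self.embeddings_[iu], self.embeddings_[iv]))
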