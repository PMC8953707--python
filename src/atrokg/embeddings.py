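"""Skip-gram node embeddings with negative sampling, trained on walk corpora.

A compact, vectorised word2vec-style trainer: center/context pairs are
extracted from random walks with the usual per-token shrunk window, negative
contexts are drawn from the unigram^0.75 noise distribution, and updates use
minibatch SGD with a linearly decaying learning rate.  Everything is driven
by a single seeded generator, so a fixed seed gives an identical table.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .features import WalkCorpus

logger = logging.getLogger(__name__)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def _extract_pairs(
    walks_idx: list[np.ndarray], window: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    centers, contexts = [], []
    for walk in walks_idx:
        n = len(walk)
        if n < 2:
            continue
        b = rng.integers(1, window + 1, size=n)  # shrunk window per token
        for i in range(n):
            lo, hi = max(0, i - int(b[i])), min(n, i + int(b[i]) + 1)
            for j in range(lo, hi):
                if j != i:
                    centers.append(walk[i])
                    contexts.append(walk[j])
    return np.asarray(centers, dtype=np.int64), np.asarray(contexts, dtype=np.int64)


def embed_nodes(
    corpus: WalkCorpus,
    dim: int = 128,
    window: int = 10,
    epochs: int = 5,
    negative: int = 5,
    seed: int = 0,
    learning_rate: float = 0.025,
    batch_size: int = 16384,
    max_step: float = 0.5,
    vocabulary: list[str] | None = None,
) -> pd.DataFrame:
    """Train skip-gram-with-negative-sampling embeddings on a walk corpus.

    Returns a DataFrame with one ``dim``-length row per node.  Nodes listed
    in ``vocabulary`` but absent from every walk keep their random
    initialisation (and are logged), so downstream consumers always find a
    vector for every graph node.
    """
    if not corpus.walks:
        raise ValueError("empty walk corpus")
    rng = np.random.default_rng(seed)
    seen = sorted({v for walk in corpus.walks for v in walk})
    vocab = sorted(set(seen) | set(vocabulary or []))
    index = {v: i for i, v in enumerate(vocab)}
    n_vocab = len(vocab)
    unseen = sorted(set(vocab) - set(seen))
    if unseen:
        logger.warning("%d nodes absent from all walks keep random vectors: %s", len(unseen), unseen[:5])

    w_in = (rng.random((n_vocab, dim)) - 0.5) / dim
    w_out = np.zeros((n_vocab, dim))

    walks_idx = [np.array([index[v] for v in walk], dtype=np.int64) for walk in corpus.walks]
    centers, contexts = _extract_pairs(walks_idx, window, rng)
    n_pairs = len(centers)
    if n_pairs == 0:
        raise ValueError("walk corpus yields no training pairs")

    counts = np.bincount(np.concatenate(walks_idx), minlength=n_vocab).astype(float)
    noise = counts**0.75
    noise /= noise.sum()

    total = epochs * n_pairs
    done = 0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, batch_size):
            idx = order[start : start + batch_size]
            c, o = centers[idx], contexts[idx]
            nb = len(c)
            neg = rng.choice(n_vocab, size=(nb, negative), p=noise)
            lr = learning_rate * max(1e-4, 1.0 - done / total)

            uc = w_in[c]  # (B, d)
            vo = w_out[o]  # (B, d)
            vn = w_out[neg]  # (B, k, d)
            g_pos = _sigmoid(np.einsum("bd,bd->b", uc, vo)) - 1.0  # (B,)
            g_neg = _sigmoid(np.einsum("bd,bkd->bk", uc, vn))  # (B, k)

            d_uc = g_pos[:, None] * vo + np.einsum("bk,bkd->bd", g_neg, vn)
            d_vo = g_pos[:, None] * uc
            d_vn = g_neg[:, :, None] * uc[:, None, :]

            # sum per-row gradients, then cap each row's step norm: frequent
            # nodes otherwise accumulate occurrence-proportional steps that
            # can blow up on large corpora
            buf_in = np.zeros_like(w_in)
            np.add.at(buf_in, c, d_uc)
            buf_out = np.zeros_like(w_out)
            np.add.at(buf_out, o, d_vo)
            np.add.at(buf_out, neg.reshape(-1), d_vn.reshape(-1, dim))
            for w, buf in ((w_in, buf_in), (w_out, buf_out)):
                step = lr * buf
                norms = np.linalg.norm(step, axis=1, keepdims=True)
                w -= step * np.minimum(1.0, max_step / np.maximum(norms, 1e-12))
            done += nb
    return pd.DataFrame(w_in, index=vocab, columns=[f"e{i}" for i in range(dim)])


def write_embeddings_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="node_id")


def read_embeddings_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="node_id")
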