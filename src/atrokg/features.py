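"""Graph-derived inputs for the link predictors.

Random-walk machinery (first- and second-order biased walks over the edge
weights), preferential-attachment scores, per-node centrality feature
tables, edge-feature combiners and the symmetric normalized adjacency used
by the graph convolutional encoder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .kg import (
    KnowledgeGraph,
    eigenvector_centrality,
    neighborhood_connectivity,
    subgraph_centrality,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Transition model  P = T^-1 A
# ---------------------------------------------------------------------------

@dataclass
class TransitionModel:
    """Row-stochastic random-walk operator of a weighted graph.

    ``P = T^-1 A`` where T is the diagonal weighted-degree matrix, so
    ``p(u,v) = w(u,v)/d_u``.  Rows of isolated nodes are undefined: they are
    zero and flagged in ``undefined_rows``.
    """

    P: np.ndarray
    nodes: list[str]
    degrees: np.ndarray
    undefined_rows: list[str]


def transition_model(kg: KnowledgeGraph) -> TransitionModel:
    a, nodes = kg.adjacency()
    d = a.sum(axis=1)
    undefined = [nodes[i] for i in np.flatnonzero(d == 0)]
    if undefined:
        logger.warning("isolated nodes have undefined transition rows: %s", undefined)
    safe = np.where(d > 0, d, 1.0)
    p = a / safe[:, None]
    return TransitionModel(P=p, nodes=nodes, degrees=d, undefined_rows=undefined)


# ---------------------------------------------------------------------------
# Biased random walks (second-order, return parameter p / in-out parameter q)
# ---------------------------------------------------------------------------

@dataclass
class WalkCorpus:
    """Node-id sequences sampled from a graph plus the sampling settings."""

    walks: list[list[str]]
    walk_length: int
    walks_per_node: int
    p: float
    q: float
    seed: int


def generate_walks(
    kg: KnowledgeGraph,
    p: float = 1.0,
    q: float = 1.0,
    walk_length: int = 80,
    walks_per_node: int = 10,
    seed: int = 0,
) -> WalkCorpus:
    """Sample biased random walks from every node.

    Steps follow edge weights modulated by the second-order bias: weight
    divided by ``p`` for returning to the previous node, unchanged for moves
    to a neighbor of the previous node, divided by ``q`` otherwise, then
    renormalized.  ``p = q = 1`` reduces to the first-order walk ``P = T^-1 A``.
    Walks from dead-end nodes are truncated.
    """
    if walk_length < 2:
        raise ValueError("walk_length must be >= 2")
    rng = np.random.default_rng(seed)
    nodes = kg.node_order()
    index = {v: i for i, v in enumerate(nodes)}
    neigh: list[np.ndarray] = []
    wts: list[np.ndarray] = []
    neigh_sets: list[set[int]] = []
    for v in nodes:
        nb = kg.neighbors(v)
        neigh.append(np.array([index[u] for u in nb], dtype=int))
        w = np.array([kg.graph.edges[v, u].get("weight", 1.0) for u in nb], dtype=float)
        wts.append(w)
        neigh_sets.append(set(neigh[-1].tolist()))
    cumw = [np.cumsum(w) for w in wts]
    first_order = p == 1.0 and q == 1.0
    walks: list[list[str]] = []
    for _ in range(walks_per_node):
        for start in range(len(nodes)):
            walk = [start]
            if len(neigh[start]) == 0:
                logger.warning("dead-end start node %r: walk truncated", nodes[start])
                walks.append([nodes[start]])
                continue
            # first step: first-order probabilities
            cw = cumw[start]
            cur = int(neigh[start][np.searchsorted(cw, rng.random() * cw[-1], side="right")])
            walk.append(cur)
            while len(walk) < walk_length:
                nb, w = neigh[cur], wts[cur]
                if len(nb) == 0:
                    logger.warning("dead-end at %r: walk truncated", nodes[cur])
                    break
                if first_order:
                    cw = cumw[cur]
                    cur = int(nb[np.searchsorted(cw, rng.random() * cw[-1], side="right")])
                    walk.append(cur)
                    continue
                prev = walk[-2]
                bias = np.where(
                    nb == prev,
                    1.0 / p,
                    np.array([1.0 if x in neigh_sets[prev] else 1.0 / q for x in nb]),
                )
                wb = w * bias
                cur = int(rng.choice(nb, p=wb / wb.sum()))
                walk.append(cur)
            walks.append([nodes[i] for i in walk])
    return WalkCorpus(
        walks=walks,
        walk_length=walk_length,
        walks_per_node=walks_per_node,
        p=p,
        q=q,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Preferential attachment and edge features
# ---------------------------------------------------------------------------

def preferential_attachment(kg: KnowledgeGraph, u: str, v: str) -> float:
    """|Gamma(u)| * |Gamma(v)| — product of neighbor-set sizes."""
    if u == v:
        raise ValueError("preferential attachment is defined for distinct nodes")
    return float(kg.graph.degree(u) * kg.graph.degree(v))


COMBINERS = ("hadamard", "mean", "concatenate", "abs-difference")


def edge_features(
    table: pd.DataFrame, u: str, v: str, combiner: str = "hadamard"
) -> np.ndarray:
    """Combine two node feature vectors into one edge feature vector."""
    return edge_feature_matrix(table, [(u, v)], combiner)[0]


def edge_feature_matrix(
    table: pd.DataFrame, pairs: Sequence[tuple[str, str]], combiner: str = "hadamard"
) -> np.ndarray:
    """Vectorised edge-feature construction for many pairs.

    ``hadamard``, ``mean`` and ``abs-difference`` are symmetric in (u, v) and
    dimension-preserving; ``concatenate`` doubles the dimension and is order
    sensitive.
    """
    if combiner not in COMBINERS:
        raise ValueError(f"unknown combiner {combiner!r}; expected one of {COMBINERS}")
    missing = sorted({n for p in pairs for n in p} - set(table.index))
    if missing:
        raise KeyError(f"nodes missing from feature table: {missing}")
    a = table.loc[[u for u, _ in pairs]].to_numpy(dtype=float)
    b = table.loc[[v for _, v in pairs]].to_numpy(dtype=float)
    if combiner == "hadamard":
        return a * b
    if combiner == "mean":
        return (a + b) / 2.0
    if combiner == "abs-difference":
        return np.abs(a - b)
    return np.hstack([a, b])


# ---------------------------------------------------------------------------
# Node feature table (centralities) and normalized adjacency
# ---------------------------------------------------------------------------

def node_feature_table(kg: KnowledgeGraph) -> pd.DataFrame:
    """Per-node centrality features: degree, eigenvector centrality,
    subgraph centrality (log-scaled for numeric range) and neighborhood
    connectivity.  Isolated nodes get neighborhood connectivity 0 so the
    table stays finite."""
    nodes = kg.node_order()
    ec = eigenvector_centrality(kg)
    sc = subgraph_centrality(kg)
    nc = [neighborhood_connectivity(kg, v) for v in nodes]
    return pd.DataFrame(
        {
            "degree": [float(kg.degree(v)) for v in nodes],
            "eigenvector_centrality": ec[nodes].to_numpy(),
            "log_subgraph_centrality": np.log(sc[nodes].to_numpy()),
            "neighborhood_connectivity": np.nan_to_num(np.asarray(nc, dtype=float)),
        },
        index=nodes,
    )


def normalized_adjacency(kg: KnowledgeGraph) -> tuple[sp.csr_matrix, list[str]]:
    """Symmetric self-looped normalized adjacency for graph convolutions.

    ``A_hat = D_bar^-1/2 (A + I) D_bar^-1/2`` with ``D_bar`` the degree matrix
    of ``A + I``.  Exactly symmetric; spectrum lies in [-1, 1].
    """
    a, nodes = kg.adjacency()
    a_bar = a + np.eye(len(nodes))
    d = a_bar.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    a_hat = a_bar * inv_sqrt[:, None] * inv_sqrt[None, :]
    a_hat = (a_hat + a_hat.T) / 2.0  # enforce exact symmetry
    return sp.csr_matrix(a_hat), nodes
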