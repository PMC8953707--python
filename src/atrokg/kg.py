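"""Typed knowledge-graph container, I/O, and node/graph-level network measures.

The central object is :class:`KnowledgeGraph`, an undirected weighted graph
whose nodes carry a biomedical type (``gene``, ``disease`` or ``drug``) and
whose edges always join nodes of *different* types.  Two concrete instances
dominate the analysis: the gene-disease knowledge graph (GDKG) and the
disease-drug knowledge graph (DDKG).

Measures implemented here are the ones used to characterise those graphs:
per-node degree, neighborhood connectivity (mean neighbor degree),
eigenvector centrality and subgraph centrality, plus whole-graph density,
average neighbor count and the adjacency spectral gap.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NODE_TYPES = ("gene", "disease", "drug")

EDGE_TABLE_COLUMNS = ["source_id", "source_type", "target_id", "target_type", "weight"]


class GraphSchemaError(ValueError):
    """Raised when an edge record violates the typed-graph schema."""


@dataclass
class KnowledgeGraph:
    """Undirected weighted graph with typed nodes.

    Wraps a :class:`networkx.Graph`; node attribute ``ntype`` holds the node
    type and edge attribute ``weight`` the positive edge weight (default 1).
    All derived orderings (adjacency rows, serialised edge lists) use sorted
    node ids so that identical graphs produce identical artifacts.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    # ------------------------------------------------------------------ build
    @classmethod
    def from_edge_table(cls, table: pd.DataFrame) -> "KnowledgeGraph":
        """Build a deduplicated graph from a typed edge table.

        ``table`` needs columns ``source_id, source_type, target_id,
        target_type`` and optionally ``weight``.  Same-type edges, self loops
        and unknown node types are rejected with the offending record.
        """
        g = nx.Graph()
        if len(table) == 0:
            return cls(g)
        missing = [c for c in EDGE_TABLE_COLUMNS[:4] if c not in table.columns]
        if missing:
            raise GraphSchemaError(f"edge table missing columns: {missing}")
        weights = table["weight"] if "weight" in table.columns else pd.Series(1.0, index=table.index)
        for row, w in zip(table.itertuples(index=False), weights):
            cls._check_record(row.source_id, row.source_type, row.target_id, row.target_type, float(w))
            g.add_node(str(row.source_id), ntype=row.source_type)
            g.add_node(str(row.target_id), ntype=row.target_type)
            g.add_edge(str(row.source_id), str(row.target_id), weight=float(w))
        return cls(g)

    @staticmethod
    def _check_record(sid, stype, tid, ttype, weight) -> None:
        record = f"({sid}[{stype}] -- {tid}[{ttype}], w={weight})"
        if stype not in NODE_TYPES or ttype not in NODE_TYPES:
            raise GraphSchemaError(f"unknown node type in record {record}")
        if stype == ttype:
            raise GraphSchemaError(f"same-type edge rejected: {record}")
        if str(sid) == str(tid):
            raise GraphSchemaError(f"self-loop rejected: {record}")
        if not np.isfinite(weight) or weight <= 0:
            raise GraphSchemaError(f"non-positive weight in record {record}")

    def add_edge(self, u: str, u_type: str, v: str, v_type: str, weight: float = 1.0) -> None:
        self._check_record(u, u_type, v, v_type, weight)
        self.graph.add_node(str(u), ntype=u_type)
        self.graph.add_node(str(v), ntype=v_type)
        self.graph.add_edge(str(u), str(v), weight=float(weight))

    # ------------------------------------------------------------------ views
    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_order(self) -> list[str]:
        """Deterministic node ordering used for all matrix representations."""
        return sorted(self.graph.nodes())

    def node_type(self, v: str) -> str:
        return self.graph.nodes[v]["ntype"]

    def nodes_of_type(self, ntype: str) -> list[str]:
        return sorted(v for v, d in self.graph.nodes(data=True) if d["ntype"] == ntype)

    def degree(self, v: str) -> int:
        return self.graph.degree(v)

    def neighbors(self, v: str) -> list[str]:
        return sorted(self.graph.neighbors(v))

    def has_edge(self, u: str, v: str) -> bool:
        return self.graph.has_edge(u, v)

    def edges(self) -> list[tuple[str, str]]:
        """Canonical (lexicographically ordered within pair) sorted edge list."""
        return sorted(tuple(sorted(e)) for e in self.graph.edges())

    def adjacency(self, nodelist: Sequence[str] | None = None) -> tuple[np.ndarray, list[str]]:
        nodes = list(nodelist) if nodelist is not None else self.node_order()
        a = nx.to_numpy_array(self.graph, nodelist=nodes, weight="weight")
        return a, nodes

    def subgraph_without_edges(self, pairs: Iterable[tuple[str, str]]) -> "KnowledgeGraph":
        """Copy of the graph with the given edges removed (nodes retained)."""
        g = self.graph.copy()
        g.remove_edges_from(pairs)
        return KnowledgeGraph(g)

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for u, v in self.edges():
            rows.append(
                {
                    "source_id": u,
                    "source_type": self.node_type(u),
                    "target_id": v,
                    "target_type": self.node_type(v),
                    "weight": self.graph.edges[u, v].get("weight", 1.0),
                }
            )
        return pd.DataFrame(rows, columns=EDGE_TABLE_COLUMNS)

    # --------------------------------------------------------------------- io
    def write_edgelist_tsv(self, path: str | Path) -> None:
        self.edge_table().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_edgelist_tsv(cls, path: str | Path) -> "KnowledgeGraph":
        return cls.from_edge_table(pd.read_csv(path, sep="\t", dtype={"source_id": str, "target_id": str}))

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, path, named_key_ids=True)

    @classmethod
    def read_graphml(cls, path: str | Path) -> "KnowledgeGraph":
        g = nx.read_graphml(path)
        out = nx.Graph()
        for v, d in g.nodes(data=True):
            out.add_node(str(v), ntype=d["ntype"])
        for u, v, d in g.edges(data=True):
            out.add_edge(str(u), str(v), weight=float(d.get("weight", 1.0)))
        return cls(out)


# ---------------------------------------------------------------------------
# Node-level measures
# ---------------------------------------------------------------------------

def neighborhood_connectivity(kg: KnowledgeGraph, v: str) -> float:
    """Mean degree of v's neighbors; NaN (undefined) for isolated nodes."""
    neigh = list(kg.graph.neighbors(v))
    if not neigh:
        logger.warning("neighborhood connectivity undefined for isolated node %r", v)
        return float("nan")
    return float(np.mean([kg.graph.degree(u) for u in neigh]))


def eigenvector_centrality(kg: KnowledgeGraph, tol: float = 1e-8, max_iter: int = 10_000) -> pd.Series:
    """Principal-eigenvector centrality of the weighted adjacency matrix.

    Computed by power iteration to ``tol``; disconnected graphs are handled
    per connected component, each component's sub-vector normalised to unit
    Euclidean norm.  Entries are nonnegative.
    """
    if kg.n_nodes == 0:
        raise ValueError("eigenvector centrality of an empty graph is undefined")
    scores = pd.Series(0.0, index=kg.node_order())
    for comp in nx.connected_components(kg.graph):
        nodes = sorted(comp)
        if len(nodes) == 1:
            scores[nodes[0]] = 1.0
            continue
        a, _ = kg.adjacency(nodes)
        # shift by +I: same principal eigenvector, but kills the -lambda_1
        # oscillation that stalls power iteration on bipartite graphs
        a_shift = a + np.eye(len(nodes))
        x = np.full(len(nodes), 1.0 / np.sqrt(len(nodes)))
        for _ in range(max_iter):
            y = a_shift @ x
            norm = np.linalg.norm(y)
            if norm == 0:  # no edges in component
                break
            y /= norm
            if np.linalg.norm(y - x) < tol:
                x = y
                break
            x = y
        scores[nodes] = np.abs(x)
    return scores


def subgraph_centrality(kg: KnowledgeGraph, v: str | None = None) -> pd.Series | float:
    """Subgraph centrality: factorially damped count of closed walks.

    ``SC(v) = sum_k (A^k)_vv / k!``, the diagonal of ``expm(A)``.  Evaluated
    through the symmetric eigendecomposition ``SC(v) = sum_j U_vj^2 e^{l_j}``,
    which sums the full series exactly.  Returns the value for ``v`` or a
    Series over all nodes.
    """
    nodes = kg.node_order()
    if not nodes:
        return pd.Series(dtype=float)
    a, _ = kg.adjacency(nodes)
    lam, u = np.linalg.eigh(a)
    sc = (u**2) @ np.exp(lam)
    series = pd.Series(sc, index=nodes)
    if v is not None:
        return float(series[v])
    return series


# ---------------------------------------------------------------------------
# Graph-level summary
# ---------------------------------------------------------------------------

@dataclass
class NetworkMeasureReport:
    """Whole-graph measures plus per-node centrality tables."""

    spectral_gap: float
    density: float
    average_neighbors: float
    node_table: pd.DataFrame  # columns: ntype, degree, neighborhood_connectivity,
    #                                     eigenvector_centrality, subgraph_centrality

    def to_json(self, path: str | Path) -> None:
        payload = {
            "spectral_gap": self.spectral_gap,
            "density": self.density,
            "average_neighbors": self.average_neighbors,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    def to_tsv(self, path: str | Path) -> None:
        self.node_table.to_csv(path, sep="\t", index_label="node_id")


def graph_summary(kg: KnowledgeGraph) -> NetworkMeasureReport:
    """Density, mean neighbor count, adjacency spectral gap and node measures.

    The spectral gap is ``lambda_1 - lambda_2`` of the weighted adjacency
    matrix (eigenvalues sorted descending).
    """
    n = kg.n_nodes
    if n < 2:
        raise ValueError("graph summary requires at least 2 nodes")
    m = kg.n_edges
    density = 2.0 * m / (n * (n - 1))
    average_neighbors = 2.0 * m / n
    a, nodes = kg.adjacency()
    lam = np.linalg.eigvalsh(a)
    spectral_gap = float(lam[-1] - lam[-2])
    ec = eigenvector_centrality(kg)
    sc = subgraph_centrality(kg)
    node_table = pd.DataFrame(
        {
            "ntype": [kg.node_type(v) for v in nodes],
            "degree": [kg.degree(v) for v in nodes],
            "neighborhood_connectivity": [neighborhood_connectivity(kg, v) for v in nodes],
            "eigenvector_centrality": ec[nodes].to_numpy(),
            "subgraph_centrality": sc[nodes].to_numpy(),
        },
        index=nodes,
    )
    return NetworkMeasureReport(spectral_gap, density, average_neighbors, node_table)
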