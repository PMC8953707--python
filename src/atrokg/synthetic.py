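"""Synthetic study systems: expression matrices with planted regulatory
structure, and gene-disease / disease-drug knowledge graphs with planted
held-out links.

The expression generator draws from a linear-Gaussian structural equation
model over a user-supplied acyclic regulatory network, emulating the
tiny-sample (3-8 observations) normalized expression matrices the analysis
starts from.  The graph generators emulate the two knowledge graphs the
pipeline studies: a bipartite gene-disease graph with heavy-tailed gene
degrees (preferential-attachment partner sampling plus block community
structure) and a disease-drug graph where every disease is linked to exactly
``drugs_per_disease`` drugs sampled with popularity bias.  A fraction of
true edges is withheld and returned as planted positives, so every
downstream learner can be evaluated without external data.

Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .kg import KnowledgeGraph
from .linkpred import LabeledEdgeSet

__all__ = [
    "RegulatoryNetworkSpec",
    "SyntheticGraphSpec",
    "simulate_expression",
    "implied_covariance",
    "random_regulatory_network",
    "true_markov_blanket",
    "simulate_gdkg",
    "simulate_ddkg",
    "with_heldout_restored",
]


# ---------------------------------------------------------------------------
# Linear-Gaussian regulatory networks
# ---------------------------------------------------------------------------

@dataclass
class RegulatoryNetworkSpec:
    """Acyclic weighted regulatory network driving the expression simulator.

    ``edges`` are ordered (parent, child) pairs; ``coefficients`` aligns with
    ``edges``; ``noise_sd`` is a scalar or per-gene mapping of nonnegative
    noise standard deviations.
    """

    node_ids: list[str]
    edges: list[tuple[str, str]] = field(default_factory=list)
    coefficients: list[float] = field(default_factory=list)
    noise_sd: float | Mapping[str, float] = 1.0

    def __post_init__(self) -> None:
        if len(self.edges) != len(self.coefficients):
            raise ValueError("coefficients must align with edges")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("node_ids must be unique")
        if not all(np.isfinite(self.coefficients)):
            raise ValueError("all coefficients must be finite")
        for v in self.node_ids:
            if self.sd(v) < 0:
                raise ValueError(f"noise_sd for {v!r} must be >= 0")
        dag = nx.DiGraph()
        dag.add_nodes_from(self.node_ids)
        dag.add_edges_from(self.edges)
        try:
            cycle = nx.find_cycle(dag)
        except nx.NetworkXNoCycle:
            self._dag = dag
        else:
            raise ValueError(f"regulatory network contains a cycle: {cycle}")

    def sd(self, node: str) -> float:
        if isinstance(self.noise_sd, Mapping):
            return float(self.noise_sd.get(node, 0.0))
        return float(self.noise_sd)

    def parents(self, node: str) -> list[str]:
        return sorted(self._dag.predecessors(node))

    def children(self, node: str) -> list[str]:
        return sorted(self._dag.successors(node))


def simulate_expression(
    spec: RegulatoryNetworkSpec, n_samples: int, seed: int = 0
) -> pd.DataFrame:
    """Sample a genes x samples expression matrix from the linear-Gaussian SEM.

    Each gene is drawn in topological order as the coefficient-weighted sum
    of its parents plus independent Gaussian noise.  Identical seeds give
    identical matrices.
    """
    if n_samples < 3:
        raise ValueError("n_samples must be >= 3")
    rng = np.random.default_rng(seed)
    coef = {e: c for e, c in zip(spec.edges, spec.coefficients)}
    values: dict[str, np.ndarray] = {}
    for node in nx.lexicographical_topological_sort(spec._dag):
        x = rng.standard_normal(n_samples) * spec.sd(node)
        for parent in spec.parents(node):
            x = x + coef[(parent, node)] * values[parent]
        values[node] = x
    mat = np.vstack([values[g] for g in spec.node_ids])
    return pd.DataFrame(
        mat, index=spec.node_ids, columns=[f"s{j + 1}" for j in range(n_samples)]
    )


def implied_covariance(spec: RegulatoryNetworkSpec) -> pd.DataFrame:
    """Closed-form covariance of the SEM: ``(I-C)^-1 D (I-C)^-T`` with
    ``C[child, parent]`` the edge coefficient and D the noise variances."""
    idx = {g: i for i, g in enumerate(spec.node_ids)}
    n = len(spec.node_ids)
    c = np.zeros((n, n))
    for (parent, child), w in zip(spec.edges, spec.coefficients):
        c[idx[child], idx[parent]] = w
    d = np.diag([spec.sd(g) ** 2 for g in spec.node_ids])
    inv = np.linalg.inv(np.eye(n) - c)
    sigma = inv @ d @ inv.T
    return pd.DataFrame(sigma, index=spec.node_ids, columns=spec.node_ids)


def random_regulatory_network(
    n_genes: int = 10,
    n_edges: int = 12,
    seed: int = 0,
    coef_range: tuple[float, float] = (0.6, 1.4),
    noise_sd: float = 1.0,
) -> RegulatoryNetworkSpec:
    """Random DAG with signed coefficients of magnitude in ``coef_range``.

    Edge directions follow a random gene ordering, guaranteeing acyclicity;
    magnitudes are bounded away from zero so conditional dependences stay
    detectable (faithfulness, in practice).
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:03d}" for i in range(n_genes)]
    order = rng.permutation(n_genes)
    candidates = [
        (genes[order[i]], genes[order[j]])
        for i in range(n_genes)
        for j in range(i + 1, n_genes)
    ]
    if n_edges > len(candidates):
        raise ValueError("too many edges requested for an acyclic network")
    pick = rng.choice(len(candidates), size=n_edges, replace=False)
    edges = [candidates[i] for i in sorted(pick)]
    mags = rng.uniform(*coef_range, size=n_edges)
    signs = rng.choice([-1.0, 1.0], size=n_edges)
    return RegulatoryNetworkSpec(
        node_ids=genes,
        edges=edges,
        coefficients=list(mags * signs),
        noise_sd=noise_sd,
    )


def true_markov_blanket(spec: RegulatoryNetworkSpec, target: str) -> set[str]:
    """Parents, children and spouses (co-parents of children) of ``target``."""
    parents = set(spec.parents(target))
    children = set(spec.children(target))
    spouses = {p for ch in children for p in spec.parents(ch)} - {target}
    return parents | children | spouses


def _is_faithful(spec: RegulatoryNetworkSpec, min_partial_corr: float) -> bool:
    """Population-level detectability screen for blanket recovery.

    For every target and every member of its true blanket, the partial
    correlation given the rest of the blanket (computed from the closed-form
    covariance) must exceed ``min_partial_corr``.  Random coefficient draws
    occasionally make collider paths cancel — a faithfulness violation under
    which no conditional-independence method can recover the blanket.
    """
    corr = implied_covariance(spec).to_numpy()
    d = np.sqrt(np.diag(corr))
    corr = corr / np.outer(d, d)
    pos = {g: i for i, g in enumerate(spec.node_ids)}
    for target in spec.node_ids:
        blanket = true_markov_blanket(spec, target)
        for member in blanket:
            cond = [pos[g] for g in blanket if g != member]
            idx = [pos[target], pos[member], *cond]
            prec = np.linalg.pinv(corr[np.ix_(idx, idx)])
            denom = np.sqrt(prec[0, 0] * prec[1, 1])
            r = 0.0 if denom == 0 else abs(prec[0, 1]) / denom
            if r < min_partial_corr:
                return False
    return True


def random_faithful_regulatory_network(
    n_genes: int = 10,
    n_edges: int = 12,
    seed: int = 0,
    min_partial_corr: float = 0.1,
    max_tries: int = 200,
    **kwargs,
) -> RegulatoryNetworkSpec:
    """Random DAG redrawn until it passes the faithfulness screen."""
    for attempt in range(max_tries):
        spec = random_regulatory_network(n_genes, n_edges, seed + 7919 * attempt, **kwargs)
        if _is_faithful(spec, min_partial_corr):
            return spec
    raise RuntimeError("no faithful network found; relax min_partial_corr")


# ---------------------------------------------------------------------------
# Knowledge-graph generators
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGraphSpec:
    """Study conditions for the synthetic GDKG/DDKG generators.

    Defaults mirror the scale of the analysed graphs: 473 genes, 100
    diseases, 98 drugs, ten drugs per disease.  ``attachment_exponent``
    controls gene-degree heterogeneity (0 gives near-uniform degrees; larger
    values stretch the max/min ratio); ``n_blocks``/``block_affinity`` plant
    community structure; ``popularity_exponent`` sets the Zipf popularity
    bias used when sampling drug partners.
    """

    n_genes: int = 473
    n_diseases: int = 100
    n_drugs: int = 98
    attachment_exponent: float = 1.0
    drugs_per_disease: int = 10
    holdout_fraction: float = 0.2
    seed: int = 0
    base_degree: int = 4
    n_blocks: int = 4
    block_affinity: float = 4.0
    popularity_exponent: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must lie strictly between 0 and 1")
        if self.drugs_per_disease > self.n_drugs:
            raise ValueError("drugs_per_disease cannot exceed n_drugs")
        if self.attachment_exponent < 0:
            raise ValueError("attachment_exponent must be >= 0")


def _gumbel_topk(weights: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Indices of a size-k sample without replacement, P(pick) ∝ weight."""
    keys = np.log(weights) + rng.gumbel(size=len(weights))
    return np.argpartition(-keys, k - 1)[:k]


def _split_holdout(
    g: nx.Graph, fraction: float, rng: np.random.Generator
) -> list[tuple[str, str]]:
    """Pick ~fraction of edges whose removal isolates no node, and remove them."""
    edges = sorted(tuple(sorted(e)) for e in g.edges())
    target = int(round(fraction * len(edges)))
    deg = dict(g.degree())
    removed: list[tuple[str, str]] = []
    for i in rng.permutation(len(edges)):
        u, v = edges[i]
        if deg[u] >= 2 and deg[v] >= 2:
            removed.append((u, v))
            deg[u] -= 1
            deg[v] -= 1
            if len(removed) == target:
                break
    if len(removed) < target:
        raise ValueError(
            f"cannot withhold {target} edges without isolating a node "
            f"(only {len(removed)} removable)"
        )
    g.remove_edges_from(removed)
    return sorted(removed)


def simulate_gdkg(spec: SyntheticGraphSpec) -> tuple[KnowledgeGraph, LabeledEdgeSet]:
    """Bipartite gene-disease graph with planted held-out positives.

    Gene degrees follow a capped Pareto draw (``base_degree`` scaled by
    ``u^-attachment_exponent``); each gene's disease partners are sampled by
    preferential attachment (weight = current disease degree + 1) modulated
    by block affinity.  A ``holdout_fraction`` of edges is withheld such
    that no node is left isolated.
    """
    if spec.n_genes < 2 or spec.n_diseases < 2:
        raise ValueError("need at least 2 genes and 2 diseases")
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i + 1:04d}" for i in range(spec.n_genes)]
    diseases = [f"D{i + 1:03d}" for i in range(spec.n_diseases)]
    gene_block = rng.integers(0, spec.n_blocks, size=spec.n_genes)
    dis_block = rng.integers(0, spec.n_blocks, size=spec.n_diseases)

    u = rng.random(spec.n_genes)
    m = np.clip(
        np.round(spec.base_degree * np.power(1.0 - u, -spec.attachment_exponent)),
        1,
        spec.n_diseases,
    ).astype(int)

    g = nx.Graph()
    g.add_nodes_from(genes, ntype="gene")
    g.add_nodes_from(diseases, ntype="disease")
    dis_degree = np.zeros(spec.n_diseases)
    for i, gene in enumerate(genes):
        affinity = np.where(dis_block == gene_block[i], spec.block_affinity, 1.0)
        w = (dis_degree + 1.0) * affinity
        for j in _gumbel_topk(w, int(m[i]), rng):
            g.add_edge(gene, diseases[j], weight=1.0)
            dis_degree[j] += 1
    # no disease may be isolated
    for j, dis in enumerate(diseases):
        if g.degree(dis) == 0:
            gene = genes[int(rng.integers(spec.n_genes))]
            g.add_edge(gene, dis, weight=1.0)

    removed = _split_holdout(g, spec.holdout_fraction, rng)
    heldout = LabeledEdgeSet(
        removed, np.ones(len(removed), dtype=int), tag="heldout", seed=spec.seed
    )
    return KnowledgeGraph(g), heldout


def simulate_ddkg(spec: SyntheticGraphSpec) -> tuple[KnowledgeGraph, LabeledEdgeSet]:
    """Disease-drug graph: every disease linked to exactly
    ``drugs_per_disease`` distinct drugs sampled with Zipf popularity bias
    and block affinity.  Drug usage weights are stored as the node attribute
    ``usage_weight`` (the generator's notion of how commonly a drug is
    used).  Drugs are never linked to each other or to genes.
    """
    if spec.n_diseases < 2 or spec.n_drugs < 2:
        raise ValueError("need at least 2 diseases and 2 drugs")
    rng = np.random.default_rng(spec.seed)
    diseases = [f"D{i + 1:03d}" for i in range(spec.n_diseases)]
    drugs = [f"R{i + 1:03d}" for i in range(spec.n_drugs)]
    dis_block = rng.integers(0, spec.n_blocks, size=spec.n_diseases)
    drug_block = rng.integers(0, spec.n_blocks, size=spec.n_drugs)
    ranks = rng.permutation(spec.n_drugs) + 1
    usage = np.power(ranks.astype(float), -spec.popularity_exponent)

    g = nx.Graph()
    g.add_nodes_from(diseases, ntype="disease")
    for r, w in zip(drugs, usage):
        g.add_node(r, ntype="drug", usage_weight=float(w))
    k = spec.drugs_per_disease
    for i, dis in enumerate(diseases):
        affinity = np.where(drug_block == dis_block[i], spec.block_affinity, 1.0)
        for j in _gumbel_topk(usage * affinity, k, rng):
            g.add_edge(dis, drugs[j], weight=1.0)

    # keep every drug in use without changing per-disease counts: swap an
    # edge from a well-connected drug over to each unused drug
    for j, drug in enumerate(drugs):
        if g.degree(drug) > 0:
            continue
        for dis in rng.permutation(diseases):
            partners = sorted(g.neighbors(dis))
            donors = [r for r in partners if g.degree(r) >= 2]
            if donors:
                g.remove_edge(dis, donors[0])
                g.add_edge(dis, drug, weight=1.0)
                break

    removed = _split_holdout(g, spec.holdout_fraction, rng)
    heldout = LabeledEdgeSet(
        removed, np.ones(len(removed), dtype=int), tag="heldout", seed=spec.seed
    )
    return KnowledgeGraph(g), heldout


def with_heldout_restored(kg: KnowledgeGraph, heldout: LabeledEdgeSet) -> KnowledgeGraph:
    """The full generated graph: retained edges plus the held-out positives."""
    g = kg.graph.copy()
    for u, v in heldout.positives:
        g.add_edge(u, v, weight=1.0)
    return KnowledgeGraph(g)
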