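import numpy as np
import pandas as pd
import pytest

from atrokg.kg import KnowledgeGraph


def star_graph(n_leaves: int = 5) -> KnowledgeGraph:
    """Star: one disease hub connected to n gene leaves."""
    kg = KnowledgeGraph()
    for i in range(n_leaves):
        kg.add_edge("hub", "disease", f"G{i + 1:02d}", "gene", 1.0)
    return kg


def complete_bipartite(n_genes: int, n_diseases: int) -> KnowledgeGraph:
    kg = KnowledgeGraph()
    for i in range(n_genes):
        for j in range(n_diseases):
            kg.add_edge(f"G{i + 1:02d}", "gene", f"D{j + 1:02d}", "disease", 1.0)
    return kg


def random_bipartite(n_genes: int, n_diseases: int, p: float, seed: int) -> KnowledgeGraph:
    """Random gene-disease graph; every node guaranteed at least one edge."""
    rng = np.random.default_rng(seed)
    kg = KnowledgeGraph()
    genes = [f"G{i + 1:02d}" for i in range(n_genes)]
    diseases = [f"D{j + 1:02d}" for j in range(n_diseases)]
    for i, g in enumerate(genes):
        for j, d in enumerate(diseases):
            if rng.random() < p:
                kg.add_edge(g, "gene", d, "disease", 1.0)
    for g in genes:
        if g not in kg.graph or kg.degree(g) == 0:
            kg.add_edge(g, "gene", diseases[int(rng.integers(n_diseases))], "disease", 1.0)
    for d in diseases:
        if d not in kg.graph or kg.degree(d) == 0:
            kg.add_edge(genes[int(rng.integers(n_genes))], "gene", d, "disease", 1.0)
    return kg


@pytest.fixture
def star5() -> KnowledgeGraph:
    return star_graph(5)


@pytest.fixture
def k22() -> KnowledgeGraph:
    """Complete bipartite 2x2: vertex-transitive, so node measures coincide."""
    return complete_bipartite(2, 2)


@pytest.fixture
def triangle_kg() -> KnowledgeGraph:
    """3-cycle using the three node types (the schema forbids same-type edges)."""
    kg = KnowledgeGraph()
    kg.add_edge("g1", "gene", "d1", "disease", 1.0)
    kg.add_edge("d1", "disease", "r1", "drug", 1.0)
    kg.add_edge("r1", "drug", "g1", "gene", 1.0)
    return kg


@pytest.fixture
def small_random_kg() -> KnowledgeGraph:
    return random_bipartite(8, 6, 0.35, seed=11)


@pytest.fixture
def triangle_adjacency() -> np.ndarray:
    return np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
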