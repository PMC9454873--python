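import networkx as nx
import numpy as np
import pytest
from hypothesis import settings

from lidcnet.io import ComplexCatalog

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def random_graph(seed: int, max_nodes: int = 50) -> nx.Graph:
    """Seeded G(n, p) with string node labels, n <= max_nodes."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, max_nodes + 1))
    p = float(rng.uniform(0.05, 0.5))
    G = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31 - 1)))
    return nx.relabel_nodes(G, {i: f"N{i:03d}" for i in G.nodes()})


def random_catalog(G: nx.Graph, seed: int) -> ComplexCatalog:
    """A few random complexes over the graph's nodes (overlaps allowed)."""
    rng = np.random.default_rng(seed)
    nodes = sorted(G.nodes())
    complexes = []
    for i in range(int(rng.integers(1, 5))):
        size = int(rng.integers(1, min(6, len(nodes)) + 1))
        members = rng.choice(nodes, size=size, replace=False)
        complexes.append((f"C{i:02d}", frozenset(members.tolist())))
    return ComplexCatalog(complexes)


@pytest.fixture
def triangle() -> nx.Graph:
    return nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def star4() -> nx.Graph:
    """Star with centre c and 4 leaves."""
    return nx.Graph([("c", f"l{i}") for i in range(4)])
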