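import itertools

import networkx as nx
import pytest

import ksimnet as ks


@pytest.fixture(scope="session")
def karate() -> nx.Graph:
    return ks.load_fixture("karate")


@pytest.fixture(scope="session")
def lesmis() -> nx.Graph:
    return ks.load_fixture("lesmis")


@pytest.fixture(scope="session")
def football() -> nx.Graph:
    return ks.load_fixture("football")


@pytest.fixture
def two_triangles_bridge() -> nx.Graph:
    """Two triangles {0,1,2} and {3,4,5} joined by the single edge 2-3."""
    return ks.build_graph([(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (2, 3)])


def hierarchy_toy(s: int = 6, pair_edges: int = 4, super_edges: int = 3) -> nx.Graph:
    """Three-level toy: 4 cliques of s nodes, cliques paired by ``pair_edges``
    edges, the two pairs joined by ``super_edges`` edges."""
    g = nx.Graph()
    cliques = [list(range(i * s, (i + 1) * s)) for i in range(4)]
    for block in cliques:
        g.add_edges_from(itertools.combinations(block, 2))
    for a, b in ((0, 1), (2, 3)):
        for j in range(pair_edges):
            g.add_edge(cliques[a][j], cliques[b][j])
    for j in range(super_edges):
        g.add_edge(cliques[1][s - 1 - j], cliques[2][s - 1 - j])
    return g


def set_partitions(items):
    """All partitions of ``items`` (restricted-growth-string enumeration)."""
    items = list(items)
    n = len(items)

    def rec(i, labels, mx):
        if i == n:
            yield {items[j]: labels[j] for j in range(n)}
            return
        for c in range(mx + 1):
            labels.append(c)
            yield from rec(i + 1, labels, mx if c < mx else mx + 1)
            labels.pop()

    yield from rec(0, [], 0)
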