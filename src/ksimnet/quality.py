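"""Partition quality measures.

All three structural measures derive from one object, the community
edge-fraction matrix e: e_ii is the fraction of edges internal to
community i, e_ij (i ≠ j) holds half of the fraction of edges running
between i and j (so the matrix is symmetric and sums to 1), and the row
sums a_i are the fraction of edge endpoints attached to community i.

* modularity     Q = Σ_i (e_ii − a_i²)          — higher is better
* MinMaxCut        = Σ_i ext(C_i) / int(C_i)    — lower is better
* coverage         = Σ_i int(C_i) / m           — higher is better

Partition agreement against a reference uses normalized mutual
information, NMI = 2·I(X;Y) / (H(X) + H(Y)) by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from sklearn.metrics import normalized_mutual_info_score

from .graph import Node, Partition, _sorted_labels


@dataclass
class EdgeFractionMatrix:
    """Per-community-pair edge counts and fractions.

    ``labels[i]`` names community i; ``counts`` is the K×K symmetric
    integer matrix with internal edge counts on the diagonal and full cut
    counts off it; ``fractions`` = counts/m with each cut edge split
    across the two symmetric cells; ``row_sums`` are the a_i.
    """

    labels: list[Node]
    counts: np.ndarray
    fractions: np.ndarray
    row_sums: np.ndarray

    def internal(self, i: int) -> int:
        return int(self.counts[i, i])

    def external(self, i: int) -> int:
        return int(self.counts[i].sum() - self.counts[i, i])


def edge_fraction_matrix(g: nx.Graph, p: Partition) -> EdgeFractionMatrix:
    """Exact edge counts/fractions between all community pairs of ``p``."""
    p.check_total(g)
    m = g.number_of_edges()
    if m == 0:
        raise ValueError("no edges")
    labels = _sorted_labels(p.labels)
    pos = {c: i for i, c in enumerate(labels)}
    k = len(labels)
    counts = np.zeros((k, k), dtype=np.int64)
    for u, v in g.edges:
        i, j = pos[p[u]], pos[p[v]]
        if i == j:
            counts[i, i] += 1
        else:
            counts[i, j] += 1
            counts[j, i] += 1
    fractions = counts / m
    off = ~np.eye(k, dtype=bool)
    fractions[off] /= 2.0  # each cut edge split across its two symmetric cells
    return EdgeFractionMatrix(labels, counts, fractions, fractions.sum(axis=1))


def modularity(g: nx.Graph, p: Partition) -> float:
    """Newman–Girvan modularity Q = Σ_i (e_ii − a_i²)."""
    e = edge_fraction_matrix(g, p)
    return float(np.trace(e.fractions) - (e.row_sums**2).sum())


def minmaxcut(g: nx.Graph, p: Partition, *, permissive: bool = False) -> float:
    """Σ_i external(C_i)/internal(C_i) over communities; 0 for a lone block.

    A community with no internal edge but external edges makes the measure
    undefined (raises), or contributes +inf under ``permissive``.
    """
    e = edge_fraction_matrix(g, p)
    total = 0.0
    for i in range(len(e.labels)):
        ext, internal = e.external(i), e.internal(i)
        if ext == 0:
            continue
        if internal == 0:
            if permissive:
                return float("inf")
            raise ValueError(f"undefined MinMaxCut: community {e.labels[i]!r} has no internal edge")
        total += ext / internal
    return total


def coverage(g: nx.Graph, p: Partition) -> float:
    """Fraction of all edges that are internal to communities, in [0, 1]."""
    e = edge_fraction_matrix(g, p)
    return float(np.trace(e.counts) / g.number_of_edges())


def nmi(x: Partition, y: Partition, *, average: str = "arithmetic") -> float:
    """Normalized mutual information between two partitions of one node set.

    ``average='arithmetic'`` gives 2I/(H(X)+H(Y)); ``'geometric'`` gives
    the √(H(X)·H(Y)) variant.  Two single-community partitions agree
    perfectly (1.0); a partition carrying no information scores 0.
    """
    if set(x) != set(y):
        raise ValueError("partitions cover different node sets")
    nodes = _sorted_labels(set(x))
    lx = {c: i for i, c in enumerate(_sorted_labels(x.labels))}
    ly = {c: i for i, c in enumerate(_sorted_labels(y.labels))}
    a = [lx[x[v]] for v in nodes]
    b = [ly[y[v]] for v in nodes]
    return float(normalized_mutual_info_score(a, b, average_method=average))
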