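"""Node-pair structural similarity indexes and deterministic neighbor ranking.

The default index, ``cn_closed``, counts common members of the *closed*
neighborhoods N[u] = {u} ∪ N(u): for an adjacent pair it always scores at
least 2 (the pair itself), which keeps the ranking informative on
triangle-free stretches while ordering pairs exactly like plain common
neighbors.  The open-neighborhood ``cn`` and seven standard normalized
link-prediction indexes are selectable by name.
"""

from __future__ import annotations

import math
from typing import Callable

import networkx as nx

from .graph import Node, label_key, node_index

# ties in floating-point similarity closer than this are broken by degree,
# then node index, not by the noise in the last bits
TIE_TOL = 1e-12


def _nbrs(g: nx.Graph, v: Node) -> set[Node]:
    return set(g.adj[v])


def _cn(g, u, v):
    return len(_nbrs(g, u) & _nbrs(g, v))


def _cn_closed(g, u, v):
    nu = _nbrs(g, u)
    nu.add(u)
    nv = _nbrs(g, v)
    nv.add(v)
    return len(nu & nv)


def _jaccard(g, u, v):
    nu, nv = _nbrs(g, u), _nbrs(g, v)
    union = len(nu | nv)
    return len(nu & nv) / union if union else 0.0


def _salton(g, u, v):
    ku, kv = g.degree[u], g.degree[v]
    return _cn(g, u, v) / math.sqrt(ku * kv) if ku and kv else 0.0


def _sorensen(g, u, v):
    ku, kv = g.degree[u], g.degree[v]
    return 2 * _cn(g, u, v) / (ku + kv) if ku + kv else 0.0


def _hpi(g, u, v):
    ku, kv = g.degree[u], g.degree[v]
    return _cn(g, u, v) / min(ku, kv) if ku and kv else 0.0


def _hdi(g, u, v):
    ku, kv = g.degree[u], g.degree[v]
    return _cn(g, u, v) / max(ku, kv) if ku and kv else 0.0


def _adamic_adar(g, u, v):
    # common neighbors of two distinct nodes have degree >= 2, so log(k) > 0
    return sum(1.0 / math.log(g.degree[w]) for w in _nbrs(g, u) & _nbrs(g, v))


def _resource_allocation(g, u, v):
    return sum(1.0 / g.degree[w] for w in _nbrs(g, u) & _nbrs(g, v))


INDEXES: dict[str, Callable[[nx.Graph, Node, Node], float]] = {
    "cn_closed": _cn_closed,
    "cn": _cn,
    "jaccard": _jaccard,
    "salton": _salton,
    "sorensen": _sorensen,
    "hpi": _hpi,
    "hdi": _hdi,
    "adamic_adar": _adamic_adar,
    "resource_allocation": _resource_allocation,
}

DEFAULT_INDEX = "cn_closed"


def similarity(g: nx.Graph, u: Node, v: Node, index: str = DEFAULT_INDEX) -> float:
    """Structural similarity of the node pair (u, v) under the named index.

    Symmetric and non-negative; 0 when the pair shares no neighborhood
    overlap.  ``u == v`` is rejected — self-similarity is undefined here.
    """
    if u == v:
        raise ValueError("self-similarity undefined")
    if u not in g or v not in g:
        raise KeyError("both nodes must belong to the graph")
    try:
        fn = INDEXES[index]
    except KeyError:
        raise ValueError(f"unknown similarity index: {index!r}") from None
    return fn(g, u, v)


def rank_neighbors(
    g: nx.Graph,
    v: Node,
    index: str = DEFAULT_INDEX,
    *,
    _index_map: dict[Node, int] | None = None,
) -> list[Node]:
    """Neighbors of ``v`` in decreasing similarity order, fully tie-broken.

    The cascade is: similarity descending (ties closer than ``TIE_TOL``
    treated as equal) → degree ascending → canonical node index ascending.
    The result is a permutation of ``adjacency(v)``; isolated nodes yield
    an empty list.
    """
    if v not in g:
        raise KeyError(f"unknown node: {v!r}")
    nbrs = list(g.adj[v])
    if not nbrs:
        return []
    idx = _index_map if _index_map is not None else node_index(g)
    fn = INDEXES[index]
    scored = sorted(
        ((fn(g, v, u), u) for u in nbrs),
        key=lambda t: (-t[0], g.degree[t[1]], idx[t[1]]),
    )
    # regroup near-equal similarities and re-sort each group by (degree, idx):
    # the primary sort above used exact floats, so only boundaries where two
    # scores differ by <= TIE_TOL but compared unequal need fixing
    out: list[tuple[float, Node]] = []
    group: list[tuple[float, Node]] = []
    for s, u in scored:
        if group and group[0][0] - s > TIE_TOL:
            group.sort(key=lambda t: (g.degree[t[1]], idx[t[1]]))
            out.extend(group)
            group = []
        group.append((s, u))
    group.sort(key=lambda t: (g.degree[t[1]], idx[t[1]]))
    out.extend(group)
    return [u for _, u in out]
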