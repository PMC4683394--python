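"""Core graph and partition containers.

Graphs are plain :class:`networkx.Graph` objects constrained to be simple
(no self-loops, no parallel edges) and undirected.  All algorithms in this
package iterate nodes in a single canonical order — sorted node labels,
falling back to string-keyed sorting for mixed label types — so every
tie-break cascade is reproducible across runs and platforms.
"""

from __future__ import annotations

import logging
from collections.abc import Hashable, Iterable, Mapping
from typing import Iterator

import networkx as nx

logger = logging.getLogger(__name__)

Node = Hashable


def label_key(label: Node):
    """Canonical sort key for node/community labels of possibly mixed types."""
    return (type(label).__name__, label) if not isinstance(label, str) else ("str", label)


def _sorted_labels(labels: Iterable[Node]) -> list[Node]:
    labels = list(labels)
    try:
        return sorted(labels)
    except TypeError:
        return sorted(labels, key=label_key)


def node_order(g: nx.Graph) -> list[Node]:
    """Nodes of ``g`` in the canonical (sorted-label) processing order."""
    return _sorted_labels(g.nodes)


def node_index(g: nx.Graph) -> dict[Node, int]:
    """Map node label -> contiguous index 0..n-1 in canonical order."""
    return {v: i for i, v in enumerate(node_order(g))}


def build_graph(edges: Iterable[tuple[Node, Node]], nodes: Iterable[Node] = ()) -> nx.Graph:
    """Build a simple undirected graph from an edge list.

    Self-loops and duplicate edges are dropped with a logged warning.
    ``nodes`` may declare extra (possibly isolated) nodes; degree-0 nodes
    are retained as first-class citizens.

    Raises
    ------
    ValueError
        If both ``edges`` and ``nodes`` are empty.
    """
    g = nx.Graph()
    g.add_nodes_from(nodes)
    self_loops = 0
    duplicates = 0
    for u, v in edges:
        if u == v:
            self_loops += 1
            g.add_node(u)
            continue
        if g.has_edge(u, v):
            duplicates += 1
            continue
        g.add_edge(u, v)
    if self_loops:
        logger.warning("dropped %d self-loop(s)", self_loops)
    if duplicates:
        logger.warning("dropped %d duplicate edge(s)", duplicates)
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph: no edges and no nodes given")
    return g


def degree(g: nx.Graph, v: Node) -> int:
    """Number of neighbors of ``v``; raises ``KeyError`` on unknown nodes."""
    if v not in g:
        raise KeyError(f"unknown node: {v!r}")
    return g.degree[v]


class Partition(Mapping):
    """A hard (total, non-overlapping) partition: node -> community label.

    Every graph node carries exactly one label and every label in use has
    at least one member.  Partitions compare equal when they induce the
    same blocks under the same labels; :meth:`as_blocksets` compares the
    grouping irrespective of label names.
    """

    __slots__ = ("_assignment",)

    def __init__(self, assignment: Mapping[Node, Node]):
        if not assignment:
            raise ValueError("empty partition")
        self._assignment = dict(assignment)

    def __getitem__(self, node: Node) -> Node:
        return self._assignment[node]

    def __iter__(self) -> Iterator[Node]:
        return iter(self._assignment)

    def __len__(self) -> int:
        return len(self._assignment)

    def __repr__(self) -> str:
        return f"Partition({len(self)} nodes, {len(self.labels)} communities)"

    def __eq__(self, other) -> bool:
        if isinstance(other, Partition):
            return self._assignment == other._assignment
        return NotImplemented

    def __hash__(self):
        return hash(frozenset(self._assignment.items()))

    @property
    def labels(self) -> set[Node]:
        return set(self._assignment.values())

    def blocks(self) -> dict[Node, set[Node]]:
        """Label -> member set."""
        out: dict[Node, set[Node]] = {}
        for v, c in self._assignment.items():
            out.setdefault(c, set()).add(v)
        return out

    def as_blocksets(self) -> frozenset[frozenset[Node]]:
        """Label-free view for comparing groupings across label schemes."""
        return frozenset(frozenset(b) for b in self.blocks().values())

    def sizes(self) -> dict[Node, int]:
        out: dict[Node, int] = {}
        for c in self._assignment.values():
            out[c] = out.get(c, 0) + 1
        return out

    def check_total(self, g: nx.Graph) -> None:
        """Raise ``ValueError`` unless the partition covers exactly ``g``'s nodes."""
        if set(self._assignment) != set(g.nodes):
            raise ValueError("partition does not cover the graph's node set")


def connected_components(g: nx.Graph) -> Partition:
    """Partition of ``g`` into maximal connected components.

    Each block is labeled by its smallest node label (canonical order), so
    component labels are stable under edge-list permutation.
    """
    assignment: dict[Node, Node] = {}
    for comp in nx.connected_components(g):
        label = _sorted_labels(comp)[0]
        for v in comp:
            assignment[v] = label
    return Partition(assignment)
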