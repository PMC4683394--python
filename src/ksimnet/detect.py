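"""The kSIM community detection algorithm.

kSIM is a deterministic bottom-up method.  Every node first picks an
*anchor*: among its k most similar neighbors, the one with the smallest
degree.  Connected unions of such node–anchor pairs form the initial
communities.  Two criteria are then enforced iteratively until stable:

* membership criterion — every node has strictly more neighbors inside
  its own community than inside any other single community;
* community criterion — every community has strictly more internal edges
  than edges to any other single community.

There is no objective function, no randomness and no dependence on an
input number of communities; every tie is broken by a fixed cascade
(similarity → degree → canonical node index), so repeated runs return the
identical partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .graph import Node, Partition, connected_components, label_key, node_order
from .similarity import DEFAULT_INDEX, rank_neighbors
from .graph import node_index as _node_index

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KsimConfig:
    """Parameters of a kSIM run.

    k
        Size of the anchor candidate set: each node considers its k most
        similar neighbors (1 ≤ k ≤ max degree; values past a node's degree
        simply mean "all neighbors").  k = 1 recovers the coarsest natural
        partition; larger k resolves smaller communities.
    index
        Name of the structural similarity index (see ``similarity.INDEXES``).
    nth_mode
        Alternative multi-resolution mode: instead of the smallest-degree
        member of the top-k, anchor to the n-th most similar neighbor
        (the least similar one when n exceeds the degree).  Off by default.
    max_iterations
        Safety cap on outer refinement passes; convergence is normally
        reached within a handful of passes.
    """

    k: int = 1
    index: str = DEFAULT_INDEX
    nth_mode: int | None = None
    max_iterations: int = 100

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.nth_mode is not None and self.nth_mode < 1:
            raise ValueError("nth_mode must be >= 1")


@dataclass
class KsimResult:
    """Output of :func:`detect`."""

    partition: Partition
    iterations: int
    isolated_nodes: list[Node]
    per_iteration_moves: list[tuple[int, int]] = field(default_factory=list)
    converged: bool = True

    @property
    def n_communities(self) -> int:
        return len(self.partition.labels)


def select_anchor(
    g: nx.Graph,
    v: Node,
    cfg: KsimConfig,
    *,
    _index_map: dict[Node, int] | None = None,
) -> Node | None:
    """The neighbor ``v`` initially joins, or ``None`` for isolated nodes.

    Default mode: among the first k entries of the similarity ranking,
    return the smallest-degree one (ties: the higher-similarity i.e.
    earlier-ranked one, then the smaller node index — both already encoded
    in the ranking order).  n-th-neighbor mode: return the n-th ranked
    neighbor, clamped to the least similar one.
    """
    if v not in g:
        raise KeyError(f"unknown node: {v!r}")
    ranked = rank_neighbors(g, v, cfg.index, _index_map=_index_map)
    return _anchor_from_ranked(g, ranked, cfg)


def _anchor_from_ranked(g: nx.Graph, ranked: list[Node], cfg: KsimConfig) -> Node | None:
    if not ranked:
        return None
    if cfg.nth_mode is not None:
        return ranked[min(cfg.nth_mode, len(ranked)) - 1]
    top = ranked[: cfg.k]
    # min() keeps the earliest-ranked candidate on equal degree, which is
    # exactly the higher-similarity-then-smaller-index tie-break
    return min(top, key=lambda u: g.degree[u])


def initial_partition(
    g: nx.Graph,
    cfg: KsimConfig,
    *,
    ranks: dict[Node, list[Node]] | None = None,
) -> Partition:
    """Communities = connected components of the node→anchor pair graph.

    Degree-0 nodes become singleton communities.  ``ranks`` may carry
    precomputed ``rank_neighbors`` output per node.
    """
    idx = _node_index(g)
    anchor_graph = nx.Graph()
    anchor_graph.add_nodes_from(g.nodes)
    for v in node_order(g):
        if ranks is not None:
            a = _anchor_from_ranked(g, ranks[v], cfg)
        else:
            a = select_anchor(g, v, cfg, _index_map=idx)
        if a is not None:
            anchor_graph.add_edge(v, a)
    return connected_components(anchor_graph)


def membership_sweep(
    g: nx.Graph,
    p: Partition,
    *,
    index: str = DEFAULT_INDEX,
    ranks: dict[Node, list[Node]] | None = None,
) -> tuple[Partition, int]:
    """One sequential pass enforcing the membership criterion.

    Nodes are visited in ascending canonical order; each is reassigned to
    the community holding the plurality of its neighbors, updates taking
    effect immediately.  A node tied for the maximum stays where it is if
    its current community is among the winners; otherwise it follows its
    most similar neighbor among the winning communities — ties propagate
    labels along the similarity ranking, like everything else here.
    Returns the updated partition and the number of moves.

    ``ranks`` may carry precomputed ``rank_neighbors`` output per node.
    """
    p.check_total(g)
    assignment = dict(p)
    moves = 0
    idx = _node_index(g)
    for v in node_order(g):
        if g.degree[v] == 0:
            continue
        tally: dict[Node, int] = {}
        for u in g.adj[v]:
            c = assignment[u]
            tally[c] = tally.get(c, 0) + 1
        best = max(tally.values())
        winners = {c for c, cnt in tally.items() if cnt == best}
        cur = assignment[v]
        if cur in winners:
            continue
        ranked = ranks[v] if ranks is not None else rank_neighbors(g, v, index, _index_map=idx)
        target = next(assignment[u] for u in ranked if assignment[u] in winners)
        assignment[v] = target
        moves += 1
    return Partition(assignment), moves


def _community_edge_counts(
    g: nx.Graph, assignment: dict[Node, Node]
) -> tuple[dict[Node, int], dict[Node, dict[Node, int]]]:
    """Internal edge counts per community and cut counts per partner pair.

    ``partners[c][c2]`` is the number of edges between communities c and c2
    (stored symmetrically).
    """
    internal: dict[Node, int] = {c: 0 for c in assignment.values()}
    partners: dict[Node, dict[Node, int]] = {c: {} for c in internal}
    for u, v in g.edges:
        cu, cv = assignment[u], assignment[v]
        if cu == cv:
            internal[cu] += 1
        else:
            partners[cu][cv] = partners[cu].get(cv, 0) + 1
            partners[cv][cu] = partners[cv].get(cu, 0) + 1
    return internal, partners


def enforce_community_criteria(g: nx.Graph, p: Partition) -> tuple[Partition, int]:
    """Merge communities until each beats every single neighbor community.

    A community C violates the criterion iff internal_edges(C) ≤ cut(C, C′)
    for some other community C′.  Communities are scanned in ascending
    (size, label) order; the first violator is merged into the community it
    shares the most cut edges with (ties: the candidate whose own internal
    edge count is smaller — the community for which those shared edges
    weigh most — then the smaller label), counts are recomputed, and the
    scan restarts until a full scan finds no violator.  Singleton
    communities of degree-0 nodes are exempt (they have no edges at all).
    """
    p.check_total(g)
    assignment = dict(p)
    internal, partners = _community_edge_counts(g, assignment)
    sizes: dict[Node, int] = {}
    members: dict[Node, list[Node]] = {}
    for v, c in assignment.items():
        sizes[c] = sizes.get(c, 0) + 1
        members.setdefault(c, []).append(v)

    merges = 0
    while True:
        violator = None
        for c in sorted(internal, key=lambda c: (sizes[c], label_key(c))):
            if sizes[c] == 1 and g.degree[members[c][0]] == 0:
                continue  # isolated node: exempt singleton
            if not partners[c]:
                continue  # no other community touches it
            if internal[c] <= max(partners[c].values()):
                violator = c
                break
        if violator is None:
            return Partition(assignment), merges

        pc = partners[violator]
        target = sorted(pc, key=lambda c2: (-pc[c2], internal[c2], label_key(c2)))[0]
        # fold violator's counts into target (cut edges between them go internal)
        internal[target] += internal[violator] + pc[target]
        for c2, w in pc.items():
            del partners[c2][violator]
            if c2 != target:
                partners[c2][target] = partners[c2].get(target, 0) + w
                partners[target][c2] = partners[target].get(c2, 0) + w
        del partners[violator], internal[violator]
        for v in members[violator]:
            assignment[v] = target
        members[target].extend(members[violator])
        sizes[target] += sizes[violator]
        del members[violator], sizes[violator]
        merges += 1


def detect(g: nx.Graph, cfg: KsimConfig | None = None) -> KsimResult:
    """Run the full kSIM pipeline on ``g``.

    Anchors and initial communities are formed once; the outer loop then
    alternates a membership sweep and community-criterion merging until a
    pass changes nothing (counted in ``iterations``, including that final
    all-zero pass) or ``max_iterations`` is hit, in which case the result
    is flagged non-converged and the current partition returned.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    cfg = cfg or KsimConfig()
    idx = _node_index(g)
    ranks = {v: rank_neighbors(g, v, cfg.index, _index_map=idx) for v in g.nodes}
    p = initial_partition(g, cfg, ranks=ranks)
    history: list[tuple[int, int]] = []
    converged = False
    iterations = 0
    while iterations < cfg.max_iterations:
        p, moves = membership_sweep(g, p, index=cfg.index, ranks=ranks)
        p, merges = enforce_community_criteria(g, p)
        iterations += 1
        history.append((moves, merges))
        logger.debug("pass %d: %d moves, %d merges", iterations, moves, merges)
        if moves == 0 and merges == 0:
            converged = True
            break
    if not converged:
        logger.warning("kSIM did not converge within %d iterations", cfg.max_iterations)
    isolated = [v for v in node_order(g) if g.degree[v] == 0]
    return KsimResult(
        partition=p,
        iterations=iterations,
        isolated_nodes=isolated,
        per_iteration_moves=history,
        converged=converged,
    )
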