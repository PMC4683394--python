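"""Reading and writing graphs and partitions.

Graph formats: plain whitespace edge lists (``#`` comments), a tolerant
GML subset (``graph [ node [ id ... ] edge [ source ... target ... ] ]``;
duplicate edges and unknown attributes are ignored with a warning, unlike
the strict stock parser, because canonical research files contain them),
and Pajek ``.net``.  Everything is coerced to a simple undirected graph.

Partitions travel as two-column TSV ``node<TAB>community`` sorted by node.
"""

from __future__ import annotations

import html
import logging
import re
from pathlib import Path

import networkx as nx

from .graph import Node, Partition, build_graph, node_order

logger = logging.getLogger(__name__)

FORMATS = ("edgelist", "gml", "pajek")


def _maybe_int(tok: str):
    try:
        return int(tok)
    except ValueError:
        return tok


def _read_edgelist(path: Path) -> nx.Graph:
    edges = []
    nodes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            toks = line.split()
            if len(toks) == 1:
                nodes.append(_maybe_int(toks[0]))  # bare node declaration
                continue
            if len(toks) > 2:
                logger.warning("%s:%d: extra columns ignored", path, ln)
            edges.append((_maybe_int(toks[0]), _maybe_int(toks[1])))
    if not edges and not nodes:
        raise ValueError(f"{path}: empty graph")
    return build_graph(edges, nodes=nodes)


_GML_TOKEN = re.compile(r"\"[^\"]*\"|\[|\]|[^\s\[\]]+")


def _gml_blocks(text: str):
    """Yield (kind, attrs) for top-level node/edge blocks of a GML file.

    Tokenizer-based so nested sub-blocks (graphics etc.) are skipped
    rather than tripping the parser.
    """
    tokens = _GML_TOKEN.findall(text)
    i, n = 0, len(tokens)
    while i < n:
        if tokens[i] in ("node", "edge") and i + 1 < n and tokens[i + 1] == "[":
            kind = tokens[i]
            i += 2
            depth = 1
            attrs: dict[str, str] = {}
            key: str | None = None
            while i < n and depth:
                t = tokens[i]
                if t == "[":
                    depth += 1
                    key = None
                elif t == "]":
                    depth -= 1
                elif depth == 1:
                    if key is None:
                        key = t
                    else:
                        attrs[key] = html.unescape(t.strip('"'))
                        key = None
                i += 1
            yield kind, attrs
        else:
            i += 1


def _read_gml(path: Path) -> nx.Graph:
    text = Path(path).read_text()
    nodes: list[Node] = []
    labels: dict[Node, Node] = {}
    edges: list[tuple[Node, Node]] = []
    for kind, attrs in _gml_blocks(text):
        if kind == "node":
            if "id" not in attrs:
                raise ValueError(f"{path}: node block without id")
            nid = _maybe_int(attrs["id"])
            nodes.append(nid)
            if "label" in attrs:
                labels[nid] = _maybe_int(attrs["label"])
        else:
            if "source" not in attrs or "target" not in attrs:
                raise ValueError(f"{path}: edge block without source/target")
            edges.append((_maybe_int(attrs["source"]), _maybe_int(attrs["target"])))
    if not nodes and not edges:
        raise ValueError(f"{path}: no node or edge blocks found")
    g = build_graph(edges, nodes=nodes)
    if labels and len(set(labels.values())) == len(labels) and set(labels) >= set(g.nodes):
        g = nx.relabel_nodes(g, labels)
    return g


def _read_pajek(path: Path) -> nx.Graph:
    mg = nx.read_pajek(path)
    edges = [(u, v) for u, v, _ in mg.edges(keys=True)]
    return build_graph(edges, nodes=list(mg.nodes))


def read_graph(path, fmt: str | None = None) -> nx.Graph:
    """Read a graph file; ``fmt`` is inferred from the suffix when omitted."""
    path = Path(path)
    if fmt is None:
        fmt = {".gml": "gml", ".net": "pajek", ".paj": "pajek"}.get(path.suffix.lower(), "edgelist")
    if fmt == "edgelist":
        return _read_edgelist(path)
    if fmt == "gml":
        return _read_gml(path)
    if fmt == "pajek":
        return _read_pajek(path)
    raise ValueError(f"unknown format: {fmt!r} (expected one of {FORMATS})")


def write_graph(g: nx.Graph, path) -> None:
    """Write a plain edge list; isolated nodes appear as bare-node lines."""
    with open(path, "w") as fh:
        for u, v in sorted(g.edges, key=lambda e: (str(e[0]), str(e[1]))):
            fh.write(f"{u} {v}\n")
        for v in node_order(g):
            if g.degree[v] == 0:
                fh.write(f"{v}\n")


def write_partition(p: Partition, path) -> None:
    """Two-column TSV ``node<TAB>community``, rows sorted by node."""
    items = sorted(p.items(), key=lambda kv: str(kv[0]))
    with open(path, "w") as fh:
        for v, c in items:
            fh.write(f"{v}\t{c}\n")


def read_partition(path) -> Partition:
    """Inverse of :func:`write_partition`; duplicate node rows are an error."""
    assignment: dict[Node, Node] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 2 tab-separated columns")
            v, c = _maybe_int(parts[0]), _maybe_int(parts[1])
            if v in assignment:
                raise ValueError(f"{path}:{ln}: duplicate node {v!r}")
            assignment[v] = c
    if not assignment:
        raise ValueError(f"{path}: empty partition file")
    return Partition(assignment)
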