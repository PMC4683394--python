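"""Canonical small benchmark networks used throughout the literature.

The catalog lists the five classics (karate, dolphins, Les Misérables,
football, polbooks) with their published sizes and known community
counts.  Three are loadable offline: karate and Les Misérables from
networkx's bundled canonical data, football from a plain-text edge list
shipped with this package.  Dolphins and polbooks are catalogued but not
redistributable from this build environment; loading them raises
:class:`FixtureUnavailable` with provenance pointers.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Callable

import networkx as nx

from .graph import Node, Partition, build_graph
from .io import read_graph, read_partition


class FixtureUnavailable(RuntimeError):
    """Raised for catalogued datasets whose data is not bundled."""


def _load_karate() -> nx.Graph:
    g = nx.karate_club_graph()
    return build_graph(g.edges, nodes=g.nodes)


def _load_lesmis() -> nx.Graph:
    g = nx.les_miserables_graph()  # edge weights (co-appearance counts) ignored
    return build_graph(g.edges, nodes=g.nodes)


def _data_path(name: str):
    return resources.files("ksimnet.data").joinpath(name)


def _load_football() -> nx.Graph:
    with resources.as_file(_data_path("football.edgelist")) as path:
        return read_graph(path, "edgelist")


def _karate_truth() -> Partition:
    g = nx.karate_club_graph()
    return Partition({v: g.nodes[v]["club"] for v in g.nodes})


def _football_truth() -> Partition:
    with resources.as_file(_data_path("football_truth.tsv")) as path:
        return read_partition(path)


@dataclass(frozen=True)
class FixtureInfo:
    name: str
    n: int
    m: int
    communities: int
    description: str
    loader: Callable[[], nx.Graph] | None = None
    truth_loader: Callable[[], Partition] | None = None

    @property
    def available(self) -> bool:
        return self.loader is not None


CATALOG: dict[str, FixtureInfo] = {
    "karate": FixtureInfo(
        "karate", 34, 78, 2, "Zachary's karate club", _load_karate, _karate_truth
    ),
    "dolphins": FixtureInfo(
        "dolphins", 62, 159, 2, "Lusseau's Doubtful Sound dolphin social network"
    ),
    "lesmis": FixtureInfo(
        "lesmis", 77, 254, 6, "Les Misérables character co-appearance (Knuth)", _load_lesmis
    ),
    "football": FixtureInfo(
        # the canonical file carries 616 edge records, 3 of them duplicates
        "football", 115, 613, 12, "US college football schedule, Fall 2000",
        _load_football, _football_truth,
    ),
    "polbooks": FixtureInfo(
        "polbooks", 105, 441, 3, "Krebs' co-purchased US politics books"
    ),
}


def load_fixture(name: str) -> nx.Graph:
    """Load a catalogued network by name."""
    try:
        info = CATALOG[name]
    except KeyError:
        raise ValueError(f"unknown fixture {name!r}; known: {sorted(CATALOG)}") from None
    if info.loader is None:
        raise FixtureUnavailable(
            f"{name!r} is catalogued but its data is not bundled; obtain the "
            f"canonical file ({info.description}, n={info.n}, m={info.m}) and "
            f"use read_graph() instead"
        )
    return info.loader()


def load_truth(name: str) -> Partition:
    """Ground-truth partition for fixtures that have one (karate, football)."""
    info = CATALOG[name]
    if info.truth_loader is None:
        raise FixtureUnavailable(f"no ground-truth partition bundled for {name!r}")
    return info.truth_loader()
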