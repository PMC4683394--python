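import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ksimnet as ks
from ksimnet.graph import Partition


def brute_force_modularity(g, p):
    """Per-pair oracle: (1/2m) Σ_ij (A_ij − k_i k_j / 2m) δ(c_i, c_j)."""
    m = g.number_of_edges()
    total = 0.0
    for u in g:
        for v in g:
            if p[u] != p[v]:
                continue
            a = 1.0 if g.has_edge(u, v) else 0.0
            total += a - g.degree[u] * g.degree[v] / (2 * m)
    return total / (2 * m)


def random_partition(g, rng, k):
    nodes = list(g.nodes)
    labels = rng.integers(0, k, size=len(nodes))
    return Partition(dict(zip(nodes, (int(c) for c in labels))))


class TestEdgeFractionMatrix:
    def test_single_community(self, karate):
        e = ks.edge_fraction_matrix(karate, Partition({v: 0 for v in karate}))
        assert e.fractions.tolist() == [[1.0]]
        assert e.row_sums.tolist() == [1.0]

    def test_two_triangles_with_bridge(self, two_triangles_bridge):
        p = Partition({0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1})
        e = ks.edge_fraction_matrix(two_triangles_bridge, p)
        assert np.diag(e.counts).tolist() == [3, 3]
        assert e.counts[0, 1] == 1

    def test_karate_factions_counts(self, karate):
        # the balanced two-faction split: 34 internal edges each side, cut 10
        p = ks.detect(karate, ks.KsimConfig(k=1)).partition
        e = ks.edge_fraction_matrix(karate, p)
        assert sorted(np.diag(e.counts).tolist()) == [34, 34]
        assert e.counts[0, 1] == 10

    def test_invariants(self, karate):
        rng = np.random.default_rng(0)
        for k in (2, 3, 5):
            e = ks.edge_fraction_matrix(karate, random_partition(karate, rng, k))
            assert e.fractions.sum() == pytest.approx(1.0)
            total = np.diag(e.counts).sum() + np.triu(e.counts, 1).sum()
            assert total == karate.number_of_edges()

    def test_empty_graph_rejected(self):
        g = ks.build_graph([], nodes=[0, 1])
        with pytest.raises(ValueError, match="no edges"):
            ks.edge_fraction_matrix(g, Partition({0: 0, 1: 0}))


class TestModularity:
    def test_one_community_is_zero(self, karate):
        assert ks.modularity(karate, Partition({v: 0 for v in karate})) == pytest.approx(0.0)

    def test_karate_ksim_partition_matches_published_value(self, karate):
        p = ks.detect(karate, ks.KsimConfig(k=1)).partition
        assert ks.modularity(karate, p) == pytest.approx(0.372, abs=5e-4)

    def test_equals_brute_force_oracle_on_random_partitions(self, karate, lesmis):
        rng = np.random.default_rng(1)
        for g in (karate, lesmis):
            for k in (1, 2, 4):
                p = random_partition(g, rng, k)
                assert ks.modularity(g, p) == pytest.approx(brute_force_modularity(g, p))

    def test_agrees_with_networkx(self, karate, football):
        for g in (karate, football):
            p = ks.detect(g, ks.KsimConfig(k=1)).partition
            blocks = [set(b) for b in p.blocks().values()]
            assert ks.modularity(g, p) == pytest.approx(
                nx.community.modularity(g, blocks), abs=1e-12
            )

    def test_relabeling_and_upper_bound(self, karate):
        rng = np.random.default_rng(2)
        p = random_partition(karate, rng, 3)
        renamed = Partition({v: f"c{c}" for v, c in p.items()})
        assert ks.modularity(karate, p) == pytest.approx(ks.modularity(karate, renamed))
        assert ks.modularity(karate, p) <= 1.0


class TestMinMaxCut:
    def test_zero_cut_partition(self):
        g = ks.build_graph([(0, 1), (0, 2), (1, 2), (3, 4), (4, 5), (3, 5)])
        p = ks.connected_components(g)
        assert ks.minmaxcut(g, p) == 0.0

    def test_karate_ksim_partition(self, karate):
        p = ks.detect(karate, ks.KsimConfig(k=1)).partition
        assert ks.minmaxcut(karate, p) == pytest.approx(0.588, abs=5e-4)

    def test_two_triangles_with_bridge(self, two_triangles_bridge):
        p = Partition({0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1})
        assert ks.minmaxcut(two_triangles_bridge, p) == pytest.approx(2 / 3)

    def test_no_internal_edge_is_undefined(self):
        g = ks.build_graph([(0, 1), (1, 2), (0, 2), (2, 3)])
        p = Partition({0: 0, 1: 0, 2: 0, 3: 3})
        with pytest.raises(ValueError, match="undefined MinMaxCut"):
            ks.minmaxcut(g, p)
        assert math.isinf(ks.minmaxcut(g, p, permissive=True))


class TestCoverage:
    def test_single_community(self, karate):
        assert ks.coverage(karate, Partition({v: 0 for v in karate})) == 1.0

    def test_karate_ksim_partition(self, karate):
        p = ks.detect(karate, ks.KsimConfig(k=1)).partition
        assert ks.coverage(karate, p) == pytest.approx(0.872, abs=5e-4)

    def test_two_triangles_with_bridge(self, two_triangles_bridge):
        p = Partition({0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1})
        assert ks.coverage(two_triangles_bridge, p) == pytest.approx(6 / 7)

    def test_cut_accounting_identity(self, karate):
        # coverage + Σ_i ext(C_i)/(2m) = 1: each cut edge is seen from both sides
        rng = np.random.default_rng(3)
        m = karate.number_of_edges()
        for k in (2, 3, 6):
            p = random_partition(karate, rng, k)
            e = ks.edge_fraction_matrix(karate, p)
            ext = sum(e.external(i) for i in range(len(e.labels)))
            assert ks.coverage(karate, p) + ext / (2 * m) == pytest.approx(1.0)

    def test_minmaxcut_zero_iff_full_coverage(self, karate, two_triangles_bridge):
        cases = [
            (karate, Partition({v: 0 for v in karate})),
            (two_triangles_bridge, Partition({0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1})),
            (karate, ks.detect(karate).partition),
        ]
        for g, p in cases:
            mmc = ks.minmaxcut(g, p, permissive=True)
            cov = ks.coverage(g, p)
            assert (mmc == 0.0) == (cov == 1.0)


class TestNmi:
    def test_identical_partitions(self, karate):
        p = ks.detect(karate).partition
        assert ks.nmi(p, p) == pytest.approx(1.0)

    def test_independence_is_zero(self):
        one = Partition({v: 0 for v in range(6)})
        singletons = Partition({v: v for v in range(6)})
        assert ks.nmi(one, singletons) == pytest.approx(0.0)

    def test_crossed_pairs_zero(self):
        x = Partition({"a": 0, "b": 0, "c": 1, "d": 1})
        y = Partition({"a": 0, "c": 0, "b": 1, "d": 1})
        assert ks.nmi(x, y) == pytest.approx(0.0)

    def test_both_single_community(self):
        x = Partition({0: "a", 1: "a"})
        y = Partition({0: "b", 1: "b"})
        assert ks.nmi(x, y) == pytest.approx(1.0)

    def test_symmetry_and_range(self, karate):
        rng = np.random.default_rng(4)
        for k in (2, 4):
            x = random_partition(karate, rng, k)
            y = random_partition(karate, rng, k + 1)
            assert ks.nmi(x, y) == pytest.approx(ks.nmi(y, x))
            assert 0.0 <= ks.nmi(x, y) <= 1.0

    def test_hand_computed_value(self):
        # X = {ab|cd}, Y = {ab|c|d}: I = H(Y|...)… frozen from the closed form
        x = Partition({"a": 0, "b": 0, "c": 1, "d": 1})
        y = Partition({"a": 0, "b": 0, "c": 1, "d": 2})
        hx = math.log(2)
        hy = -(0.5 * math.log(0.5) + 2 * 0.25 * math.log(0.25))
        i = hx  # X is fully determined by Y
        assert ks.nmi(x, y) == pytest.approx(2 * i / (hx + hy))

    def test_geometric_variant(self):
        x = Partition({"a": 0, "b": 0, "c": 1, "d": 2})
        y = Partition({"a": 0, "b": 0, "c": 1, "d": 1})
        hx = -(0.5 * math.log(0.5) + 2 * 0.25 * math.log(0.25))
        hy = math.log(2)
        assert ks.nmi(x, y, average="geometric") == pytest.approx(hy / math.sqrt(hx * hy))

    def test_differing_node_sets_rejected(self):
        with pytest.raises(ValueError):
            ks.nmi(Partition({0: 0}), Partition({1: 0}))


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.integers(2, 5))
def test_modularity_oracle_on_random_graphs_and_partitions(seed, k):
    g = nx.gnp_random_graph(10, 0.35, seed=seed)
    if g.number_of_edges() == 0:
        return
    rng = np.random.default_rng(seed)
    p = random_partition(g, rng, k)
    assert ks.modularity(g, p) == pytest.approx(brute_force_modularity(g, p))
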