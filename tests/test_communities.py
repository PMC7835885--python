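"""Community detection, modularity, map equation, partition comparison,
cluster contraction."""

import itertools

import networkx as nx
import numpy as np
import pytest

import physnet as pn


def set_partitions(items):
    """All partitions of a small set (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


class TestLouvain:
    def test_two_cliques_bridge_matches_exhaustive_maximum(self, two_cliques_bridge):
        """Louvain finds the globally modularity-optimal partition of the
        8-node two-clique graph (checked against all 4140 partitions)."""
        g = two_cliques_bridge
        part = pn.louvain(g, seed=0)
        groups = {frozenset(v) for v in part.community_nodes().values()}
        assert groups == {frozenset(range(4)), frozenset(range(4, 8))}
        best = max(
            nx.community.modularity(g, p) for p in set_partitions(list(g.nodes))
        )
        assert part.modularity == pytest.approx(best, abs=1e-12)

    def test_reported_q_equals_independent_formula(self):
        for seed in range(3):
            g = nx.gnm_random_graph(25, 70, seed=seed)
            rng = np.random.default_rng(seed)
            for u, v in g.edges:
                g[u][v]["weight"] = float(rng.uniform(0.1, 1.0))
            part = pn.louvain(g, seed=seed)
            comms = [set(v) for v in part.community_nodes().values()]
            ref = nx.community.modularity(g, comms, weight="weight")
            assert part.modularity == pytest.approx(ref, abs=1e-12)

    def test_single_clique_is_one_community_with_zero_q(self):
        part = pn.louvain(nx.complete_graph(5), seed=0)
        assert part.n_communities == 1
        assert part.modularity == pytest.approx(0.0, abs=1e-12)

    def test_same_seed_same_partition(self):
        g = nx.gnm_random_graph(40, 120, seed=5)
        assert pn.louvain(g, seed=3).membership == pn.louvain(g, seed=3).membership

    def test_empty_edge_set_gives_singletons(self):
        part = pn.louvain(nx.empty_graph(4), seed=0)
        assert part.n_communities == 4 and part.modularity is None

    def test_beats_planted_partition_modularity(self, planted_spec):
        table, planted = pn.generate_cohort(planted_spec(1))
        net = pn.build_network(pn.spearman_matrix(table), 0.001)
        part = pn.louvain(net, seed=1)
        planted_q = pn.weighted_modularity(net, planted.membership)
        assert part.modularity >= planted_q - 1e-9


class TestInfomap:
    def test_two_cliques_bridge_matches_louvain_and_reduces_codelength(
        self, two_cliques_bridge
    ):
        g = two_cliques_bridge
        im = pn.infomap_two_level(g, seed=0)
        lv = pn.louvain(g, seed=0)
        assert im.membership == lv.membership
        all_in_one = {u: 1 for u in g}
        assert im.codelength <= pn.map_equation(g, all_in_one)
        assert im.codelength == pytest.approx(pn.map_equation(g, im.membership))

    def test_codelength_of_planted_partition_beats_random_relabeling(
        self, two_cliques_bridge
    ):
        """Independent map-equation evaluation over candidate partitions: the
        planted bipartition has the smallest L(M) among tested candidates."""
        g = two_cliques_bridge
        planted = {u: 1 if u < 4 else 2 for u in g}
        L_planted = pn.map_equation(g, planted)
        rng = np.random.default_rng(0)
        for _ in range(20):
            labels = rng.integers(1, 3, size=8)
            candidate = {u: int(labels[u]) for u in g}
            assert L_planted <= pn.map_equation(g, candidate) + 1e-12

    def test_single_edge_merges_into_one_module(self):
        g = nx.Graph([(0, 1)])
        im = pn.infomap_two_level(g, seed=0)
        assert im.n_communities == 1
        assert pn.map_equation(g, {0: 1, 1: 1}) < pn.map_equation(g, {0: 1, 1: 2})

    def test_same_seed_same_partition(self):
        g = nx.gnm_random_graph(40, 120, seed=7)
        a = pn.infomap_two_level(g, seed=2)
        b = pn.infomap_two_level(g, seed=2)
        assert a.membership == b.membership

    def test_isolates_become_singletons(self):
        g = nx.complete_graph(4)
        g.add_node("iso")
        im = pn.infomap_two_level(g, seed=0)
        lone = [c for c, m in im.community_nodes().items() if m == ["iso"]]
        assert len(lone) == 1


class TestSubcluster:
    def test_subcluster_splits_nested_structure(self, two_cliques_bridge):
        g = two_cliques_bridge
        part = pn.Partition({u: 1 for u in g}, None, "manual")
        subs = pn.subcluster(g, part, seed=0)
        assert subs[1].n_communities == 2

    def test_singleton_community(self):
        g = nx.Graph()
        g.add_node("a")
        part = pn.Partition({"a": 1}, None, "manual")
        subs = pn.subcluster(g, part, seed=0)
        assert subs[1].membership == {"a": 1}

    def test_never_crosses_parent_boundaries(self, two_cliques_bridge):
        g = two_cliques_bridge
        part = pn.louvain(g, seed=0)
        subs = pn.subcluster(g, part, seed=0)
        for label, sub in subs.items():
            assert set(sub.membership) == set(
                u for u, c in part.membership.items() if c == label
            )


class TestPartitionComparison:
    def test_identical_partitions(self):
        p = pn.Partition({1: 1, 2: 1, 3: 2}, None, "a")
        assert pn.rand_index(p, p) == 1.0
        assert pn.variation_of_information(p, p) == 0.0

    def test_pair_enumeration_example(self):
        p1 = pn.Partition({1: 1, 2: 1, 3: 2, 4: 2}, None, "a")
        p2 = pn.Partition({1: 1, 2: 2, 3: 3, 4: 4}, None, "b")
        assert pn.rand_index(p1, p2) == pytest.approx(4 / 6)
        assert pn.variation_of_information(p1, p2) == pytest.approx(np.log(2))

    def test_mismatched_node_sets_raise(self):
        p1 = pn.Partition({1: 1}, None, "a")
        p2 = pn.Partition({2: 1}, None, "b")
        with pytest.raises(ValueError):
            pn.rand_index(p1, p2)

    def test_adjusted_rand_is_chance_corrected(self):
        rng = np.random.default_rng(0)
        nodes = range(60)
        p1 = pn.Partition({u: int(rng.integers(1, 5)) for u in nodes}, None, "a")
        p2 = pn.Partition({u: int(rng.integers(1, 5)) for u in nodes}, None, "b")
        assert abs(pn.adjusted_rand_index(p1, p2)) < 0.15
        assert pn.rand_index(p1, p2) > 0.5  # unadjusted stays high by chance


class TestContraction:
    def test_components_partition_gives_no_edges(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        part = pn.Partition({u: 1 if u < 3 else 2 for u in g}, None, "cc")
        cg = pn.contract_clusters(g, part)
        assert cg.graph.number_of_edges() == 0
        assert cg.graph.number_of_nodes() == 2

    def test_parallel_edges_and_weight_conservation(self):
        g = nx.Graph()
        g.add_edge("a1", "a2", weight=0.5)
        g.add_edge("b1", "b2", weight=0.5)
        for u, v, w in [("a1", "b1", 0.1), ("a1", "b2", 0.2), ("a2", "b1", 0.3)]:
            g.add_edge(u, v, weight=w)
        part = pn.Partition({"a1": 1, "a2": 1, "b1": 2, "b2": 2}, None, "m")
        cg = pn.contract_clusters(g, part)
        assert cg.graph.number_of_edges() == 3
        total = sum(d["weight"] for _, _, d in cg.graph.edges(data=True))
        assert total == pytest.approx(0.6)

    def test_anchor_is_strongest_member(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.9)
        g.add_edge("a", "c", weight=0.9)
        g.add_edge("c", "d", weight=0.1)
        part = pn.Partition({"a": 1, "b": 1, "c": 1, "d": 2}, None, "m")
        cg = pn.contract_clusters(g, part)
        assert cg.anchors[1] == "a"


class TestPlantedRecovery:
    def test_pipeline_recovers_planted_blocks(self, planted_spec):
        """Louvain and the map equation both recover the planted blocks on a
        6-block cohort, and agree with each other."""
        hits_lv = hits_agree = 0
        for seed in range(8):
            table, planted = pn.generate_cohort(planted_spec(seed))
            net = pn.build_network(pn.spearman_matrix(table), 0.001)
            lv = pn.louvain(net, seed=seed)
            im = pn.infomap_two_level(net, seed=seed)
            hits_lv += pn.adjusted_rand_index(lv, planted) >= 0.8
            hits_agree += pn.rand_index(lv, im) >= 0.7
        assert hits_lv >= 7
        assert hits_agree >= 7
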