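"""Community structure: Louvain and map-equation clustering, modularity,
subclustering, partition comparison, and cluster contraction.

Louvain runs through networkx's seeded implementation; the map-equation
search runs through igraph's InfoMap with the two-level description length
L(M) evaluated in-package (bits), so every reported codelength is reproducible
from the membership alone.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Dict, Optional

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics

from ._graph import WEIGHT, PhysioNetwork, as_graph, node_order, to_igraph


@dataclass
class Partition:
    """Node -> community labeling with its modularity score.

    Labels are contiguous integers from 1; ``codelength`` is the two-level map
    equation in bits when produced by the map-equation method.
    """

    membership: Dict
    modularity: Optional[float]
    method: str
    seed: Optional[int] = None
    codelength: Optional[float] = None

    def labels(self, nodes) -> np.ndarray:
        return np.array([self.membership[u] for u in nodes])

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))

    def community_nodes(self) -> Dict:
        out: Dict = {}
        for u, c in self.membership.items():
            out.setdefault(c, []).append(u)
        return out


@dataclass
class ClusterGraph:
    """Communities contracted to single nodes; inter-community edges kept
    individually as a multigraph. Each contracted node is anchored at the
    strongest member of its community (for layout reuse)."""

    graph: nx.MultiGraph
    anchors: Dict  # community label -> anchor node

    def simple_projection(self) -> nx.Graph:
        """Collapse parallel edges, summing weights (for path-based metrics)."""
        g = nx.Graph()
        g.add_nodes_from(self.graph.nodes(data=True))
        for u, v, data in self.graph.edges(data=True):
            w = data.get(WEIGHT, 1.0)
            if g.has_edge(u, v):
                g[u][v][WEIGHT] += w
            else:
                g.add_edge(u, v, **{WEIGHT: w})
        return g


def _canonical_membership(groups, nodes) -> Dict:
    """Relabel communities 1..k deterministically (by smallest member)."""
    groups = [sorted(c, key=str) for c in groups]
    groups.sort(key=lambda c: str(c[0]))
    membership = {}
    for label, members in enumerate(groups, start=1):
        for u in members:
            membership[u] = label
    for u in nodes:
        membership.setdefault(u, 0)
    return membership


def weighted_modularity(net, membership: Dict, weight: str = WEIGHT) -> float:
    """Newman weighted modularity Q = (1/2W) sum_ij (w_ij - s_i s_j / 2W) d_ij."""
    g = as_graph(net)
    two_w = sum(d.get(weight, 1.0) for _, _, d in g.edges(data=True)) * 2.0
    if two_w == 0:
        raise ValueError("modularity undefined on an edgeless graph")
    strength = dict(g.degree(weight=weight))
    inside: Dict = {}
    stot: Dict = {}
    for u, v, d in g.edges(data=True):
        if membership[u] == membership[v]:
            inside[membership[u]] = inside.get(membership[u], 0.0) + d.get(weight, 1.0)
    for u in g.nodes:
        stot[membership[u]] = stot.get(membership[u], 0.0) + strength[u]
    q = 0.0
    for c, s in stot.items():
        q += inside.get(c, 0.0) / (two_w / 2.0) - (s / two_w) ** 2
    return q


def louvain(net, resolution: float = 1.0, seed: int | None = None) -> Partition:
    """Two-phase greedy weighted-modularity optimization (Louvain).

    Node visiting order is shuffled by ``seed``; the returned Q is the exact
    weighted modularity of the final membership.
    """
    g = as_graph(net)
    if g.number_of_edges() == 0:
        membership = _canonical_membership([[u] for u in g.nodes], g.nodes)
        return Partition(membership, None, "louvain", seed)
    groups = nx.community.louvain_communities(
        g, weight=WEIGHT, resolution=resolution, seed=seed
    )
    membership = _canonical_membership(groups, g.nodes)
    q = weighted_modularity(g, membership)
    return Partition(membership, q, "louvain", seed)


def map_equation(net, membership: Dict, weight: str = WEIGHT) -> float:
    """Two-level map equation L(M) in bits for the stationary walk.

    On an undirected weighted graph the walker's stationary probability is
    proportional to node strength; module exit probability is the total weight
    of boundary edges over 2W. Strength-0 nodes contribute nothing.
    """
    g = as_graph(net)
    two_w = sum(d.get(weight, 1.0) for _, _, d in g.edges(data=True)) * 2.0
    if two_w == 0:
        return 0.0
    strength = dict(g.degree(weight=weight))
    p = {u: strength[u] / two_w for u in g.nodes}
    q_exit: Dict = {}
    for u, v, d in g.edges(data=True):
        cu, cv = membership[u], membership[v]
        if cu != cv:
            w = d.get(weight, 1.0)
            q_exit[cu] = q_exit.get(cu, 0.0) + w / two_w
            q_exit[cv] = q_exit.get(cv, 0.0) + w / two_w
    modules: Dict = {}
    for u in g.nodes:
        modules.setdefault(membership[u], []).append(u)

    def h(probs):
        tot = sum(probs)
        if tot <= 0:
            return 0.0
        return -sum(x / tot * math.log2(x / tot) for x in probs if x > 0)

    q_tot = sum(q_exit.values())
    L = q_tot * h(list(q_exit.values())) if q_tot > 0 else 0.0
    for c, members in modules.items():
        qc = q_exit.get(c, 0.0)
        probs = [p[u] for u in members] + [qc]
        pc = sum(probs)
        L += pc * h(probs)
    return L


def infomap_two_level(net, seed: int | None = None) -> Partition:
    """Two-level map-equation clustering on the weighted graph.

    Isolates become singleton modules. The reported codelength is the
    in-package L(M) of the returned membership; modularity of the same
    membership is reported alongside for comparability with Louvain.
    """
    g = as_graph(net)
    nodes = node_order(g)
    if g.number_of_edges() == 0:
        membership = _canonical_membership([[u] for u in nodes], nodes)
        return Partition(membership, None, "infomap", seed, codelength=0.0)
    h, order = to_igraph(g, nodes=nodes)
    state = random.Random(seed if seed is not None else 0)
    ig.set_random_number_generator(state)
    try:
        cl = h.community_infomap(edge_weights="capacity", trials=10)
    finally:
        ig.set_random_number_generator(random)
    groups: Dict = {}
    for vid, mod in enumerate(cl.membership):
        groups.setdefault(mod, []).append(order[vid])
    membership = _canonical_membership(list(groups.values()), nodes)
    q = weighted_modularity(g, membership)
    return Partition(
        membership, q, "infomap", seed, codelength=map_equation(g, membership)
    )


_METHODS = {"louvain": louvain, "infomap": infomap_two_level}


def cluster(net, method: str = "louvain", seed: int | None = None, **kw) -> Partition:
    try:
        fn = _METHODS[method]
    except KeyError:
        raise ValueError(f"unknown clustering method {method!r}") from None
    return fn(net, seed=seed, **kw)


def subcluster(net, part: Partition, method: str = "louvain", seed: int | None = None) -> Dict:
    """Cluster each community's induced subgraph as an independent network."""
    g = as_graph(net)
    if set(part.membership) != set(g.nodes):
        raise ValueError("partition does not cover the node set")
    out: Dict = {}
    for label, members in part.community_nodes().items():
        sub = g.subgraph(members).copy()
        out[label] = cluster(sub, method=method, seed=seed)
    return out


def _aligned_labels(p1: Partition, p2: Partition):
    n1, n2 = set(p1.membership), set(p2.membership)
    if n1 != n2:
        raise ValueError("partitions are over different node sets")
    nodes = sorted(n1, key=str)
    return p1.labels(nodes), p2.labels(nodes)


def rand_index(p1: Partition, p2: Partition) -> float:
    """Plain (unadjusted) Rand index (a + d) / C(n, 2)."""
    a, b = _aligned_labels(p1, p2)
    return float(skmetrics.rand_score(a, b))


def adjusted_rand_index(p1: Partition, p2: Partition) -> float:
    a, b = _aligned_labels(p1, p2)
    return float(skmetrics.adjusted_rand_score(a, b))


def variation_of_information(p1: Partition, p2: Partition) -> float:
    """VI = H(p1) + H(p2) - 2 I(p1; p2), in nats."""
    a, b = _aligned_labels(p1, p2)
    mi = skmetrics.mutual_info_score(a, b)
    h1 = skmetrics.mutual_info_score(a, a)
    h2 = skmetrics.mutual_info_score(b, b)
    return float(max(h1 + h2 - 2.0 * mi, 0.0))


def contract_clusters(net, part: Partition) -> ClusterGraph:
    """Contract each community to one node; keep every inter-community edge.

    The contracted node is anchored at the member with the greatest strength
    (ties broken by node id); intra-community edges are dropped; the
    inter-community edge multiset is preserved exactly, weights included.
    """
    from .topology import node_strength

    g = as_graph(net)
    if set(part.membership) != set(g.nodes):
        raise ValueError("partition does not cover the node set")
    strength = node_strength(g)
    anchors = {}
    mg = nx.MultiGraph()
    for label, members in sorted(part.community_nodes().items()):
        anchor = sorted(members, key=lambda u: (-strength[u], str(u)))[0]
        anchors[label] = anchor
        mg.add_node(label, anchor=anchor, members=sorted(members, key=str))
    for u, v, d in g.edges(data=True):
        cu, cv = part.membership[u], part.membership[v]
        if cu != cv:
            mg.add_edge(cu, cv, source=u, target=v, **{WEIGHT: d.get(WEIGHT, 1.0)})
    return ClusterGraph(mg, anchors)
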