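"""Permutation inference for network statistics and two-network comparison.

Conditionally uniform graph (CUG) tests ask whether an observed statistic
(transitivity, density, path length, ...) is extreme relative to random
graphs conditioned on size or edge count; the quadratic assignment procedure
(QAP) asks whether the correlation between two networks' adjacency matrices
(gcor) survives random node relabeling. Both operate Monte-Carlo style with
add-one-smoothed p-values, so a p of exactly zero is impossible.

CUG operates on the binarized graph: "uniform given the edges" is ill-posed
for continuous weights. gcor defaults to the weighted adjacencies with 0 for
absent edges (capturing both presence and strength); a binary variant is a
flag away.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from ._graph import WEIGHT, PhysioNetwork, as_graph, node_order

DEFAULT_R = 1000


@dataclass
class PermutationTestResult:
    observed: float
    null_draws: np.ndarray
    p_greater: float
    p_lower: float
    mode: str
    R: int
    seed: Optional[int] = None
    resampled: int = 0  # draws discarded because the statistic was undefined


def _smoothed_p(observed: float, draws: np.ndarray) -> tuple:
    R = draws.size
    p_greater = (1.0 + np.sum(draws >= observed)) / (R + 1.0)
    p_lower = (1.0 + np.sum(draws <= observed)) / (R + 1.0)
    return float(p_greater), float(p_lower)


def cug_test(
    net,
    statistic: Callable[[nx.Graph], float],
    mode: str = "edges",
    R: int = DEFAULT_R,
    seed: int | None = None,
) -> PermutationTestResult:
    """Conditionally uniform graph test of a binary-graph statistic.

    mode="size": each possible edge Bernoulli(0.5); mode="edges" (and
    "dyad_census", equivalent for undirected graphs): uniform over graphs
    with the observed edge count. Draws on which the statistic is undefined
    are resampled and counted.
    """
    if R < 99:
        raise ValueError("R must be at least 99")
    if mode not in ("size", "edges", "dyad_census"):
        raise ValueError(f"unknown CUG mode {mode!r}")
    g = as_graph(net)
    n = g.number_of_nodes()
    m = g.number_of_edges()
    binary = nx.Graph()
    binary.add_nodes_from(range(n))
    relabel = {u: i for i, u in enumerate(node_order(g))}
    binary.add_edges_from((relabel[u], relabel[v]) for u, v in g.edges())
    observed = float(statistic(binary))
    rng = np.random.default_rng(seed)
    draws = np.empty(R)
    resampled = 0
    i = 0
    guard = 0
    while i < R:
        s = int(rng.integers(2**31 - 1))
        if mode == "size":
            r = nx.gnp_random_graph(n, 0.5, seed=s)
        else:
            r = nx.gnm_random_graph(n, m, seed=s)
        try:
            val = float(statistic(r))
        except Exception:
            val = np.nan
        if np.isnan(val):
            resampled += 1
            guard += 1
            if guard > 100 * R:
                raise RuntimeError("statistic undefined on almost every draw")
            continue
        draws[i] = val
        i += 1
    p_greater, p_lower = _smoothed_p(observed, draws)
    return PermutationTestResult(
        observed, draws, p_greater, p_lower, mode, R, seed, resampled
    )


def _aligned_adjacency(net, ids: Sequence, binary: bool = False) -> np.ndarray:
    g = as_graph(net)
    A = nx.to_numpy_array(g.subgraph(ids), nodelist=list(ids), weight=WEIGHT)
    if binary:
        A = (A > 0).astype(float)
    return A


def _shared_ids(net1, net2) -> list:
    shared = sorted(set(as_graph(net1).nodes) & set(as_graph(net2).nodes), key=str)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared nodes")
    return shared


def _triangle(A: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(A.shape[0], k=1)
    return A[iu]


def gcor(net1, net2, aligned_ids: Optional[Sequence] = None, binary: bool = False) -> float:
    """Graph correlation: Pearson r of the aligned upper adjacency triangles.

    Absent edges contribute 0, so the statistic reflects both edge presence
    and strength (or presence only with ``binary=True``).
    """
    ids = list(aligned_ids) if aligned_ids is not None else _shared_ids(net1, net2)
    x = _triangle(_aligned_adjacency(net1, ids, binary))
    y = _triangle(_aligned_adjacency(net2, ids, binary))
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("adjacency triangle has zero variance; gcor undefined")
    return float(np.corrcoef(x, y)[0, 1])


def qap_test(
    net1,
    net2,
    aligned_ids: Optional[Sequence] = None,
    R: int = DEFAULT_R,
    seed: int | None = None,
    binary: bool = False,
) -> PermutationTestResult:
    """QAP test of gcor under simultaneous row/column relabeling of net2.

    The one-sided p_greater is the headline value; the null draws are
    retained for plotting.
    """
    if R < 99:
        raise ValueError("R must be at least 99")
    ids = list(aligned_ids) if aligned_ids is not None else _shared_ids(net1, net2)
    A1 = _aligned_adjacency(net1, ids, binary)
    A2 = _aligned_adjacency(net2, ids, binary)
    x = _triangle(A1)
    y = _triangle(A2)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("adjacency triangle has zero variance; QAP undefined")
    observed = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    n = len(ids)
    draws = np.empty(R)
    for r in range(R):
        perm = rng.permutation(n)
        yp = _triangle(A2[np.ix_(perm, perm)])
        draws[r] = np.corrcoef(x, yp)[0, 1]
    p_greater, p_lower = _smoothed_p(observed, draws)
    return PermutationTestResult(observed, draws, p_greater, p_lower, "qap", R, seed)


def shared_subgraph(net, ids: Sequence) -> PhysioNetwork:
    """Induced subgraph on ``ids`` with edges and attributes preserved."""
    g = as_graph(net)
    unknown = [i for i in ids if i not in g]
    if unknown:
        raise ValueError(f"unknown node id(s): {unknown}")
    sub = g.subgraph(ids).copy()
    alpha = net.alpha if isinstance(net, PhysioNetwork) else 1.0
    return PhysioNetwork(sub, alpha=alpha)


@dataclass
class NetworkComparison:
    """Correspondence between two networks over their shared variables."""

    shared_nodes: List
    node_strength_rho: float
    node_strength_p: float
    eigencentrality_rho: float
    eigencentrality_p: float
    flow_betweenness_rho: float
    flow_betweenness_p: float
    edge_weight_rho: Optional[float]
    edge_weight_p: Optional[float]
    n_shared_edges: int
    gcor: float
    qap: PermutationTestResult
    cluster_rand: Optional[float] = None
    cluster_vi: Optional[float] = None


def compare_networks(
    net1,
    net2,
    clusterings: Optional[tuple] = None,
    R: int = DEFAULT_R,
    seed: int | None = None,
) -> NetworkComparison:
    """Compare two networks over their shared nodes.

    Spearman correlations of node strength, eigencentrality, and flow
    betweenness (computed on each full network, restricted to shared nodes);
    edge-weight correlation over edges present in both; gcor + QAP on the
    shared-node subgraphs; Rand index and variation of information between
    the supplied clusterings restricted to shared nodes.
    """
    from . import centrality as _c
    from . import communities as _comm
    from . import topology as _t

    shared = _shared_ids(net1, net2)
    g1, g2 = as_graph(net1), as_graph(net2)

    def _spear(v1, v2):
        res = stats.spearmanr(v1, v2)
        return float(res.statistic), float(res.pvalue)

    s1 = _t.node_strength(g1)[shared]
    s2 = _t.node_strength(g2)[shared]
    strength_rho, strength_p = _spear(s1, s2)
    e1 = _c.eigencentrality(g1).values[shared]
    e2 = _c.eigencentrality(g2).values[shared]
    eig_rho, eig_p = _spear(e1, e2)
    f1 = _c.flow_betweenness(g1).values[shared]
    f2 = _c.flow_betweenness(g2).values[shared]
    flow_rho, flow_p = _spear(f1, f2)

    shared_edges = [
        (u, v)
        for u, v in g1.subgraph(shared).edges()
        if g2.has_edge(u, v)
    ]
    if len(shared_edges) >= 3:
        w1 = [g1[u][v].get(WEIGHT, 1.0) for u, v in shared_edges]
        w2 = [g2[u][v].get(WEIGHT, 1.0) for u, v in shared_edges]
        edge_rho, edge_p = _spear(w1, w2)
    else:
        edge_rho = edge_p = None

    sub1 = shared_subgraph(net1, shared)
    sub2 = shared_subgraph(net2, shared)
    g = gcor(sub1, sub2, aligned_ids=shared)
    qap = qap_test(sub1, sub2, aligned_ids=shared, R=R, seed=seed)

    rand = vi = None
    if clusterings is not None:
        p1, p2 = clusterings
        m1 = {u: p1.membership[u] for u in shared}
        m2 = {u: p2.membership[u] for u in shared}
        q1 = _comm.Partition(m1, None, p1.method)
        q2 = _comm.Partition(m2, None, p2.method)
        rand = _comm.rand_index(q1, q2)
        vi = _comm.variation_of_information(q1, q2)

    return NetworkComparison(
        shared_nodes=shared,
        node_strength_rho=strength_rho,
        node_strength_p=strength_p,
        eigencentrality_rho=eig_rho,
        eigencentrality_p=eig_p,
        flow_betweenness_rho=flow_rho,
        flow_betweenness_p=flow_p,
        edge_weight_rho=edge_rho,
        edge_weight_p=edge_p,
        n_shared_edges=len(shared_edges),
        gcor=g,
        qap=qap,
        cluster_rand=rand,
        cluster_vi=vi,
    )
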