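"""Node centralities: eigencentrality, Freeman flow betweenness, edge
betweenness, Freeman centralization, and centrality assortativity.

Eigencentrality and flow betweenness use the rho**2 edge weights (influence
through strong correlations, capacity for flow); edge betweenness counts
unweighted shortest paths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from ._graph import WEIGHT, as_graph, node_order, to_igraph


@dataclass
class CentralityVector:
    measure: str
    values: pd.Series  # node -> real
    normalization: str = "raw"


def eigencentrality(net, tol: float = 1e-10, max_iter: int = 100_000) -> CentralityVector:
    """Leading eigenvector of the weighted adjacency, rescaled so max = 1.

    Computed by power iteration on A + I (the shift keeps the iteration
    aperiodic without changing the Perron vector). On disconnected graphs the
    mass concentrates on the component with the largest leading eigenvalue.
    """
    g = as_graph(net)
    nodes = node_order(g)
    n = len(nodes)
    if g.number_of_edges() == 0:
        warnings.warn("eigencentrality of an edgeless graph is all zeros")
        return CentralityVector("eigencentrality", pd.Series(0.0, index=nodes), "max=1")
    A = nx.to_numpy_array(g, nodelist=nodes, weight=WEIGHT)
    x = np.ones(n)
    for _ in range(max_iter):
        y = A @ x + x
        y /= y.max()
        if np.max(np.abs(y - x)) <= tol * np.max(np.abs(y)):
            x = y
            break
        x = y
    else:  # pragma: no cover - convergence guard
        warnings.warn("power iteration did not reach tolerance")
    x = np.clip(x, 0.0, None)
    x /= x.max()
    return CentralityVector("eigencentrality", pd.Series(x, index=nodes), "max=1")


def _all_pairs_maxflow(h) -> np.ndarray:
    """All-pairs max-flow matrix via the Gomory–Hu tree.

    The max flow between two vertices equals the minimum 'flow' edge on their
    (unique) Gomory–Hu tree path; one tree gives all C(n,2) values.
    """
    n = h.vcount()
    M = np.zeros((n, n))
    if n < 2 or h.ecount() == 0:
        return M
    tree = h.gomory_hu_tree(capacity="capacity")
    adj = [[] for _ in range(n)]
    for e in tree.es:
        u, v = e.tuple
        f = e["flow"]
        adj[u].append((v, f))
        adj[v].append((u, f))
    for root in range(n):
        # DFS carrying the minimum edge flow seen from root
        stack = [(root, np.inf)]
        seen = [False] * n
        seen[root] = True
        while stack:
            u, mn = stack.pop()
            for v, f in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    val = min(mn, f)
                    M[root, v] = val
                    stack.append((v, val))
    return M


def flow_betweenness(net, normalized: bool = False) -> CentralityVector:
    """Freeman flow betweenness with edge capacities = rho**2 weights.

    f(i) = sum over pairs j < k (both != i) of maxflow(j,k) minus the same
    max flow with node i deleted. ``normalized`` divides each f(i) by the
    total pairwise max flow not involving i.
    """
    g = as_graph(net)
    nodes = node_order(g)
    n = len(nodes)
    if n < 3:
        raise ValueError("flow betweenness needs at least 3 nodes")
    h, _ = to_igraph(g, nodes=nodes)
    full = _all_pairs_maxflow(h)
    f = np.zeros(n)
    denom = np.zeros(n)
    others_cache = list(range(n))
    for i in range(n):
        keep = [v for v in others_cache if v != i]
        sub = h.induced_subgraph(keep)
        red = _all_pairs_maxflow(sub)
        for a, b in combinations(range(n - 1), 2):
            j, k = keep[a], keep[b]
            f[i] += full[j, k] - red[a, b]
            denom[i] += full[j, k]
    if normalized:
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(denom > 0, f / denom, 0.0)
        tag = "fraction-of-flow"
    else:
        tag = "raw"
    return CentralityVector("flow_betweenness", pd.Series(f, index=nodes), tag)


def edge_betweenness(net) -> dict:
    """Unweighted shortest-path edge betweenness (fractional path counts).

    Returns {frozenset({u, v}): value} with values summed over unordered node
    pairs, so an edge of a path graph a-b-c scores 2 (pairs ab and ac).
    """
    g = as_graph(net)
    eb = nx.edge_betweenness_centrality(g, normalized=False, weight=None)
    return {frozenset(e): float(v) for e, v in eb.items()}


def centralization(cv, denominator: str = "observed") -> float:
    """Freeman centralization of a centrality vector.

    ``observed``: sum_i (c_max - c_i) / ((n-1) * c_max), in [0, 1].
    ``degree_star``: divide by (n-1)(n-2), the maximum attainable sum for raw
    degree centrality (Freeman's canonical star case).
    """
    values = cv.values if isinstance(cv, CentralityVector) else pd.Series(cv)
    c = values.to_numpy(dtype=float)
    n = c.size
    if n < 2:
        raise ValueError("centralization needs at least 2 nodes")
    cmax = c.max()
    spread = float((cmax - c).sum())
    if denominator == "observed":
        if cmax == 0:
            return 0.0
        return spread / ((n - 1) * cmax)
    if denominator == "degree_star":
        return spread / ((n - 1) * (n - 2))
    raise ValueError(f"unknown denominator {denominator!r}")


def centrality_assortativity(net, cv) -> float:
    """Newman continuous-attribute assortativity of a centrality over edges.

    Pearson correlation of endpoint centralities with each undirected edge
    counted in both orientations.
    """
    g = as_graph(net)
    values = cv.values if isinstance(cv, CentralityVector) else pd.Series(cv)
    edges = list(g.edges())
    if len(edges) < 2:
        raise ValueError("assortativity needs at least 2 edges")
    x = np.array([values[u] for u, v in edges] + [values[v] for u, v in edges])
    y = np.array([values[v] for u, v in edges] + [values[u] for u, v in edges])
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("centrality constant over edge endpoints")
    return float(np.corrcoef(x, y)[0, 1])


def degree_centrality(net) -> CentralityVector:
    g = as_graph(net)
    return CentralityVector(
        "degree", pd.Series({u: float(d) for u, d in g.degree()}).sort_index(key=lambda i: i.map(str)), "raw"
    )
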