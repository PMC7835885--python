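"""Shared graph plumbing: PhysioNetwork container and networkx/igraph bridges."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import igraph as ig
import networkx as nx

WEIGHT = "weight"  # edge attribute holding the squared Spearman rho


@dataclass
class PhysioNetwork:
    """Undirected weighted biomarker network.

    Edge attributes: ``weight`` (rho**2, the link strength), ``rho`` (signed
    Spearman correlation), ``p`` (two-sided significance) and ``n_obs``
    (pairwise-complete sample count). ``alpha`` records the p-value threshold
    that produced the edge set; isolated variables are kept as nodes.
    """

    graph: nx.Graph
    alpha: float = 1.0

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def copy(self) -> "PhysioNetwork":
        return PhysioNetwork(self.graph.copy(), self.alpha)


def as_graph(net) -> nx.Graph:
    """Accept a PhysioNetwork or a bare networkx Graph."""
    if isinstance(net, PhysioNetwork):
        return net.graph
    if isinstance(net, nx.Graph):
        return net
    raise TypeError(f"expected PhysioNetwork or networkx.Graph, got {type(net)!r}")


def node_order(net) -> list:
    """Stable node ordering used whenever a graph is flattened to a matrix."""
    return sorted(as_graph(net).nodes, key=str)


def to_igraph(net, nodes: Iterable | None = None, weight: str | None = WEIGHT):
    """Convert to igraph, returning (graph, node list in vertex order).

    ``weight=None`` drops weights (binary structure). Node names are kept in
    the ``name`` vertex attribute.
    """
    g = as_graph(net)
    nodes = list(nodes) if nodes is not None else node_order(g)
    index = {u: i for i, u in enumerate(nodes)}
    edges = []
    caps = []
    for u, v, data in g.edges(data=True):
        edges.append((index[u], index[v]))
        caps.append(float(data.get(weight, 1.0)) if weight else 1.0)
    h = ig.Graph(n=len(nodes), edges=edges, directed=False)
    h.vs["name"] = [str(u) for u in nodes]
    if weight is not None:
        h.es["capacity"] = caps
    return h, nodes
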