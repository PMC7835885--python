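"""Whole-network topology metrics for weighted biomarker networks.

The panel mirrors what is conventionally reported for correlation networks in
physiology: density, Krackhardt connectedness and efficiency, hop-based
characteristic path length, Barrat weighted transitivity and clustering,
node strength, small-world indices against analytic and simulated random
baselines, and a log-log binned scale-free fitting index.

Path metrics are unweighted (hop counts); edge weights enter only through the
Barrat clustering coefficients and node strength.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._graph import WEIGHT, as_graph, node_order


class UndefinedMetricError(ValueError):
    """Raised when a metric is not defined for the given graph."""


@dataclass
class TopologySummary:
    """One-row topology record for a network.

    ``swi`` is the analytic small-world index (clustering / path-length ratio
    against k_bar/n and ln(n)/ln(k_bar) baselines); ``smallworldness`` is the
    Humphries–Gurney sigma with Monte-Carlo Erdos–Renyi baselines. Optional
    fields are None when the metric is undefined for the graph at hand.
    """

    size: int
    edges: int
    density: float
    efficiency: float
    connectedness: float
    L: Optional[float] = None
    T: Optional[float] = None
    CC: Optional[float] = None
    swi: Optional[float] = None
    smallworldness: Optional[float] = None
    scale_free_r2: Optional[float] = None
    scale_free_slope: Optional[float] = None
    eigencentrality_centralization: Optional[float] = None
    eigencentrality_assortativity: Optional[float] = None
    flow_betweenness_centralization: Optional[float] = None
    flow_betweenness_assortativity: Optional[float] = None
    reciprocity: float = 1.0  # identically 1 on undirected graphs

    def table_record(self) -> dict:
        """Record keyed by the conventional summary-table field names."""
        return {
            "Size": self.size,
            "Edges": self.edges,
            "Density": self.density,
            "Efficiency": self.efficiency,
            "Connectedness": self.connectedness,
            "L": self.L,
            "T": self.T,
            "CC": self.CC,
            "SWI": self.swi,
            "Smallworldness": self.smallworldness,
            "Eigencentrality centralization": self.eigencentrality_centralization,
            "Eigencentrality assortativity": self.eigencentrality_assortativity,
            "Flow betweenness centralization": self.flow_betweenness_centralization,
            "Flow betweenness assortativity": self.flow_betweenness_assortativity,
            "Scale-free fitting index": self.scale_free_r2,
        }


def density(net) -> float:
    """Edges divided by the number of unordered node pairs."""
    g = as_graph(net)
    n = g.number_of_nodes()
    if n < 2:
        raise UndefinedMetricError("density undefined for fewer than 2 nodes")
    return g.number_of_edges() / (n * (n - 1) / 2)


def connectedness(net) -> float:
    """Krackhardt connectedness: fraction of node pairs joined by some path."""
    g = as_graph(net)
    n = g.number_of_nodes()
    if n < 2:
        raise UndefinedMetricError("connectedness undefined for fewer than 2 nodes")
    reachable = sum(
        len(c) * (len(c) - 1) // 2 for c in nx.connected_components(g)
    )
    return reachable / (n * (n - 1) / 2)


def efficiency(net) -> float:
    """Krackhardt efficiency: 1 minus the fraction of redundant edges.

    An edge is redundant if it exceeds the size - components edges of a
    spanning forest; the fraction is taken over the redundancy capacity
    C(size, 2) - (size - components). Trees score 1, complete graphs 0.
    """
    g = as_graph(net)
    n = g.number_of_nodes()
    if n < 2:
        raise UndefinedMetricError("efficiency undefined for fewer than 2 nodes")
    m = g.number_of_edges()
    c = nx.number_connected_components(g)
    spanning = n - c
    denom = n * (n - 1) / 2 - spanning
    if denom <= 0:
        return 1.0
    return float(np.clip(1.0 - (m - spanning) / denom, 0.0, 1.0))


def path_length(net) -> float:
    """Characteristic path length: mean hop distance over reachable pairs."""
    g = as_graph(net)
    total = 0
    pairs = 0
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        sub = g.subgraph(comp)
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total += sum(dists.values())
            pairs += len(dists) - 1
    if pairs == 0:
        raise UndefinedMetricError("no reachable node pairs")
    # each unordered pair counted twice
    return total / pairs


def barrat_local_clustering(net, weight: str = WEIGHT) -> pd.Series:
    """Barrat weighted local clustering coefficient per node.

    c_i = 1/(s_i (k_i - 1)) * sum over ordered connected neighbor pairs (j, h)
    of (w_ij + w_ih)/2 — each triangle at i counts twice, so with unit weights
    this reduces to the ordinary local clustering 2 t_i / (k_i (k_i - 1)).
    Nodes with degree < 2 get NaN (no defined coefficient).
    """
    g = as_graph(net)
    out = {}
    for i in g.nodes:
        k = g.degree(i)
        if k < 2:
            out[i] = np.nan
            continue
        s = sum(d.get(weight, 1.0) for _, _, d in g.edges(i, data=True))
        acc = 0.0
        nbrs = list(g.neighbors(i))
        for j, h in combinations(nbrs, 2):
            if g.has_edge(j, h):
                # (w_ij + w_ih)/2 per ordered pair = (w_ij + w_ih) per unordered
                acc += g[i][j].get(weight, 1.0) + g[i][h].get(weight, 1.0)
        out[i] = acc / (s * (k - 1)) if s > 0 else np.nan
    return pd.Series(out, dtype=float)


def clustering_metrics(net, weight: str = WEIGHT) -> tuple:
    """Global Barrat transitivity T and mean clustering coefficient CC.

    T is the k_i(k_i-1)-weighted mean of local Barrat coefficients (equals the
    classical global transitivity at unit weights); CC is their plain mean.
    Only nodes with degree >= 2 contribute.
    """
    g = as_graph(net)
    local = barrat_local_clustering(g, weight=weight)
    mask = local.notna()
    if not mask.any():
        raise UndefinedMetricError("no node with degree >= 2")
    degs = np.array([g.degree(i) for i in local.index[mask]], dtype=float)
    vals = local[mask].to_numpy()
    wts = degs * (degs - 1)
    T = float(np.average(vals, weights=wts))
    CC = float(vals.mean())
    return T, CC


def node_strength(net, weight: str = WEIGHT) -> pd.Series:
    """Sum of incident edge weights per node; isolates get 0."""
    g = as_graph(net)
    order = node_order(g)
    deg = dict(g.degree(weight=weight))
    return pd.Series({u: float(deg.get(u, 0.0)) for u in order})


def _main_component(g: nx.Graph) -> nx.Graph:
    comp = max(nx.connected_components(g), key=len)
    return g.subgraph(comp)


def small_world(net, B: int = 100, seed: int | None = None) -> tuple:
    """Small-world index and Monte-Carlo smallworldness of the main component.

    SWI = (C/C_rand)/(L/L_rand) with the analytic Erdos–Renyi baselines
    C_rand = k_bar/n and L_rand = ln(n)/ln(k_bar); C is the unweighted global
    transitivity and L the hop-based characteristic path length.
    ``smallworldness`` (Humphries–Gurney sigma) replaces the analytic baselines
    with averages over B seeded G(n, m) graphs; it is None when B = 0.
    """
    g = _main_component(as_graph(net))
    n = g.number_of_nodes()
    m = g.number_of_edges()
    kbar = 2 * m / n if n else 0.0
    if kbar <= 1:
        raise UndefinedMetricError("mean degree <= 1: small-world baselines undefined")
    C = nx.transitivity(g)
    L = path_length(g)
    c_rand = kbar / n
    l_rand = math.log(n) / math.log(kbar)
    swi = (C / c_rand) / (L / l_rand)
    if B <= 0:
        return swi, None
    rng = np.random.default_rng(seed)
    cs, ls = [], []
    for _ in range(B):
        r = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31 - 1)))
        cs.append(nx.transitivity(r))
        try:
            ls.append(path_length(r))
        except UndefinedMetricError:
            continue
    c_mc = float(np.mean(cs)) if cs else np.nan
    l_mc = float(np.mean(ls)) if ls else np.nan
    if not (c_mc > 0 and l_mc > 0):
        return swi, None
    sigma = (C / c_mc) / (L / l_mc)
    return swi, sigma


def scale_free_fit(net, nbins: int = 10) -> tuple:
    """Scale-free fitting index: R^2 and slope of the binned log-log degree fit.

    Non-isolated degrees are binned into ``nbins`` equal-width bins; per
    nonempty bin the mean degree and empirical frequency are regressed as
    log10 p(d_k) on log10 d_k by ordinary least squares.
    """
    g = as_graph(net)
    degrees = np.array([d for _, d in g.degree() if d > 0], dtype=float)
    if degrees.size == 0:
        raise UndefinedMetricError("no non-isolated node")
    edges = np.linspace(degrees.min(), degrees.max(), nbins + 1)
    edges[-1] += 1e-9
    idx = np.digitize(degrees, edges) - 1
    dk, pk = [], []
    for b in range(nbins):
        sel = idx == b
        if sel.any():
            dk.append(degrees[sel].mean())
            pk.append(sel.mean())
    if len(dk) < 2:
        raise UndefinedMetricError("fewer than 2 nonempty degree bins")
    res = stats.linregress(np.log10(dk), np.log10(pk))
    return float(res.rvalue**2), float(res.slope)


def summarize(
    net,
    B: int = 100,
    seed: int | None = None,
    nbins: int = 10,
    include_centrality: bool = False,
) -> TopologySummary:
    """Compute the full topology panel, recording undefined metrics as None.

    ``include_centrality`` adds eigencentrality / flow-betweenness Freeman
    centralizations and assortativities (flow betweenness is the expensive
    part; skip it inside threshold scans).
    """
    g = as_graph(net)
    out = TopologySummary(
        size=g.number_of_nodes(),
        edges=g.number_of_edges(),
        density=density(g),
        efficiency=efficiency(g),
        connectedness=connectedness(g),
    )
    try:
        out.L = path_length(g)
    except UndefinedMetricError:
        pass
    try:
        out.T, out.CC = clustering_metrics(g)
    except UndefinedMetricError:
        pass
    try:
        out.swi, out.smallworldness = small_world(g, B=B, seed=seed)
    except UndefinedMetricError:
        pass
    try:
        out.scale_free_r2, out.scale_free_slope = scale_free_fit(g, nbins=nbins)
    except UndefinedMetricError:
        pass
    if include_centrality:
        from . import centrality as _c

        try:
            ec = _c.eigencentrality(g)
            out.eigencentrality_centralization = _c.centralization(ec)
            out.eigencentrality_assortativity = _c.centrality_assortativity(g, ec)
        except (UndefinedMetricError, ValueError):
            pass
        try:
            fb = _c.flow_betweenness(g)
            out.flow_betweenness_centralization = _c.centralization(fb)
            out.flow_betweenness_assortativity = _c.centrality_assortativity(g, fb)
        except (UndefinedMetricError, ValueError):
            pass
    return out
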