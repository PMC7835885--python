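"""Spearman correlation matrices, significance, and network construction.

The correlation backbone of the pipeline: pairwise-complete Spearman rho with
midranks for ties, two-sided significance from t = rho * sqrt((n-2)/(1-rho^2))
on n-2 degrees of freedom, an adjacency rule keeping pairs with p below a
threshold alpha (edge weight = rho^2, sign and p retained), and the threshold
scan used to pick alpha as the smallest value that keeps the network
connected enough.

No multiple-testing correction is applied by default: the threshold scan over
a grid of alphas is the sensitivity analysis. A Bonferroni/BH option exists
on :func:`build_network` for completeness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._graph import WEIGHT, PhysioNetwork
from .cohort import CohortTable

DEFAULT_GRID = (0.05, 0.01, 5e-3, 1e-3, 5e-4, 1e-4, 1e-5, 1e-6)


@dataclass
class CorrelationResult:
    """Pairwise Spearman rho, p, and sample-count matrices.

    All matrices are symmetric DataFrames sharing the variable order;
    diagonal rho = 1 and p = 0 by convention. Untestable pairs (fewer than 4
    pairwise-complete observations, or a constant column on the complete
    subset) carry rho = NaN and p = 1, and never become edges.
    """

    rho: pd.DataFrame
    p: pd.DataFrame
    n_obs: pd.DataFrame

    @property
    def rho2(self) -> pd.DataFrame:
        return self.rho**2

    @property
    def variables(self) -> List[str]:
        return list(self.rho.columns)


def spearman_pvalue(rho: float, n: int) -> float:
    """Two-sided p for a Spearman rho on n observations (t approximation)."""
    if n < 4:
        return 1.0
    if np.isnan(rho):
        return 1.0
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def _pvalue_matrix(rho: np.ndarray, n_obs: np.ndarray) -> np.ndarray:
    p = np.ones_like(rho)
    valid = (~np.isnan(rho)) & (n_obs >= 4)
    r = rho[valid]
    n = n_obs[valid]
    out = np.empty(r.shape)
    unit = np.abs(r) >= 1.0
    out[unit] = 0.0
    rr = r[~unit]
    nn = n[~unit]
    t = rr * np.sqrt((nn - 2) / (1.0 - rr * rr))
    out[~unit] = 2.0 * stats.t.sf(np.abs(t), df=nn - 2)
    p[valid] = out
    np.fill_diagonal(p, 0.0)
    return p


def spearman_matrix(table) -> CorrelationResult:
    """Spearman correlation matrix over pairwise-complete observations.

    Ranks use midranks for ties and are recomputed on each pair's complete
    subset, so rho is exactly the Pearson correlation of the rank vectors.
    With no missing data this reduces to one ranking per column.
    """
    values = table.values if isinstance(table, CohortTable) else pd.DataFrame(table)
    X = values.to_numpy(dtype=float)
    n, p = X.shape
    cols = list(values.columns)
    nan_mask = np.isnan(X)
    if not nan_mask.any():
        ranks = np.apply_along_axis(stats.rankdata, 0, X)
        sd = ranks.std(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rho = np.corrcoef(ranks, rowvar=False)
        rho[sd == 0, :] = np.nan
        rho[:, sd == 0] = np.nan
        np.fill_diagonal(rho, 1.0)
        n_obs = np.full((p, p), n)
    else:
        rho = np.full((p, p), np.nan)
        n_obs = np.zeros((p, p), dtype=int)
        np.fill_diagonal(rho, 1.0)
        for i in range(p):
            n_obs[i, i] = int((~nan_mask[:, i]).sum())
            for j in range(i + 1, p):
                both = ~(nan_mask[:, i] | nan_mask[:, j])
                m = int(both.sum())
                n_obs[i, j] = n_obs[j, i] = m
                if m < 4:
                    continue
                xi = stats.rankdata(X[both, i])
                yj = stats.rankdata(X[both, j])
                if np.ptp(xi) == 0 or np.ptp(yj) == 0:
                    continue
                r = np.corrcoef(xi, yj)[0, 1]
                rho[i, j] = rho[j, i] = r
    pmat = _pvalue_matrix(rho, np.asarray(n_obs, dtype=float))
    idx = pd.Index(cols)
    return CorrelationResult(
        rho=pd.DataFrame(rho, index=idx, columns=idx),
        p=pd.DataFrame(pmat, index=idx, columns=idx),
        n_obs=pd.DataFrame(np.asarray(n_obs), index=idx, columns=idx),
    )


def build_network(
    corr: CorrelationResult,
    alpha: float,
    meta: Optional[pd.DataFrame] = None,
    correction: Optional[str] = None,
) -> PhysioNetwork:
    """Threshold the correlation matrix into a weighted network.

    Edge (i, j) present iff p_ij < alpha; weight = rho^2, with signed rho, p,
    and the pairwise sample count kept as edge attributes. Isolated variables
    stay in the node set. ``correction`` in {None, "bonferroni", "bh"} adjusts
    the p matrix before thresholding (off by default).
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    variables = corr.variables
    pmat = corr.p.to_numpy().copy()
    if correction is not None:
        iu = np.triu_indices(len(variables), k=1)
        pv = pmat[iu]
        if correction == "bonferroni":
            adj = np.minimum(pv * pv.size, 1.0)
        elif correction == "bh":
            order = np.argsort(pv)
            ranked = pv[order] * pv.size / np.arange(1, pv.size + 1)
            ranked = np.minimum.accumulate(ranked[::-1])[::-1]
            adj = np.empty_like(pv)
            adj[order] = np.minimum(ranked, 1.0)
        else:
            raise ValueError(f"unknown correction {correction!r}")
        pmat[iu] = adj
        pmat[(iu[1], iu[0])] = adj
    g = nx.Graph()
    if meta is not None:
        meta_idx = meta.set_index("short_name")
        for v in variables:
            attrs = meta_idx.loc[v].to_dict() if v in meta_idx.index else {}
            g.add_node(v, **attrs)
    else:
        g.add_nodes_from(variables)
    rho = corr.rho.to_numpy()
    n_obs = corr.n_obs.to_numpy()
    for i in range(len(variables)):
        for j in range(i + 1, len(variables)):
            r = rho[i, j]
            if np.isnan(r):
                continue
            if pmat[i, j] < alpha:
                g.add_edge(
                    variables[i],
                    variables[j],
                    **{
                        WEIGHT: float(r * r),
                        "rho": float(r),
                        "p": float(corr.p.iat[i, j]),
                        "n_obs": int(n_obs[i, j]),
                    },
                )
    return PhysioNetwork(g, alpha=alpha)


@dataclass
class ThresholdScanResult:
    """Topology panel along a decreasing grid of p-value thresholds."""

    alphas: List[float]
    records: pd.DataFrame  # one row per alpha
    strengths: Dict[float, pd.Series] = field(default_factory=dict)


def threshold_scan(
    corr: CorrelationResult,
    grid: Sequence[float] = DEFAULT_GRID,
    cluster_methods: Sequence[str] = ("louvain",),
    seed: int | None = None,
    B: int = 20,
    meta: Optional[pd.DataFrame] = None,
) -> ThresholdScanResult:
    """Rebuild the network at each alpha and record the topology panel.

    Metrics undefined at some alpha (e.g., the scale-free fit on a near-empty
    graph) are recorded as NaN and the scan continues. Modularity is recorded
    per requested clustering method.
    """
    from . import communities, topology

    grid = sorted({float(a) for a in grid}, reverse=True)
    for a in grid:
        if not 0.0 < a <= 1.0:
            raise ValueError("grid alphas must be in (0, 1]")
    rows = []
    strengths: Dict[float, pd.Series] = {}
    for a in grid:
        net = build_network(corr, a, meta=meta)
        summ = topology.summarize(net, B=B, seed=seed)
        row = {
            "alpha": a,
            "size": summ.size,
            "edges": summ.edges,
            "density": summ.density,
            "efficiency": summ.efficiency,
            "connectedness": summ.connectedness,
            "L": summ.L,
            "T": summ.T,
            "CC": summ.CC,
            "swi": summ.swi,
            "smallworldness": summ.smallworldness,
            "scale_free_r2": summ.scale_free_r2,
            "mean_strength": float(topology.node_strength(net).mean()),
        }
        for method in cluster_methods:
            try:
                part = communities.cluster(net, method=method, seed=seed)
                row[f"modularity_{method}"] = part.modularity
            except ValueError:
                row[f"modularity_{method}"] = np.nan
        rows.append(row)
        strengths[a] = topology.node_strength(net)
    records = pd.DataFrame(rows)
    for col in records.columns:
        if records[col].dtype == object:
            records[col] = pd.to_numeric(records[col], errors="coerce")
    return ThresholdScanResult(alphas=list(grid), records=records, strengths=strengths)


def select_threshold(scan: ThresholdScanResult, min_connectedness: float = 0.95) -> float:
    """Smallest alpha on the grid keeping connectedness >= min_connectedness.

    If no alpha qualifies, the largest grid alpha is returned with a warning.
    """
    if scan.records.empty:
        raise ValueError("empty threshold scan")
    rec = scan.records.sort_values("alpha", ascending=False)
    ok = rec[rec["connectedness"] >= min_connectedness]
    if ok.empty:
        warnings.warn(
            "no threshold satisfies the connectedness constraint; "
            "returning the largest alpha"
        )
        return float(rec["alpha"].iloc[0])
    return float(ok["alpha"].min())
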