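"""Readers and writers for the pipeline's file formats.

CSV for tables, edge lists, memberships and curves; GraphML for networks
(attribute-rich and portable across toolkits); JSON for reports. GraphML
round-trips preserve node ids, the edge set, and every edge attribute.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict

import networkx as nx
import numpy as np
import pandas as pd

from ._graph import WEIGHT, PhysioNetwork, as_graph
from .correlation import CorrelationResult, ThresholdScanResult
from .robustness import AttackCurve


def write_correlation_csv(corr: CorrelationResult, prefix) -> None:
    prefix = Path(prefix)
    corr.rho.to_csv(prefix.with_suffix(".rho.csv"))
    corr.p.to_csv(prefix.with_suffix(".p.csv"))
    corr.n_obs.to_csv(prefix.with_suffix(".n_obs.csv"))


def read_correlation_csv(prefix) -> CorrelationResult:
    prefix = Path(prefix)
    rho = pd.read_csv(prefix.with_suffix(".rho.csv"), index_col=0)
    p = pd.read_csv(prefix.with_suffix(".p.csv"), index_col=0)
    n_obs = pd.read_csv(prefix.with_suffix(".n_obs.csv"), index_col=0)
    return CorrelationResult(rho=rho, p=p, n_obs=n_obs)


def write_edge_list(net, path) -> None:
    g = as_graph(net)
    rows = [
        {
            "source_id": u,
            "target_id": v,
            "rho": d.get("rho", np.nan),
            "rho2": d.get(WEIGHT, np.nan),
            "p": d.get("p", np.nan),
            "n_obs": d.get("n_obs", np.nan),
        }
        for u, v, d in g.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source_id", "target_id", "rho", "rho2", "p", "n_obs"]).to_csv(
        path, index=False
    )


def write_graphml(net, path) -> None:
    g = as_graph(net).copy()
    if isinstance(net, PhysioNetwork):
        g.graph["alpha"] = net.alpha
    # GraphML holds scalars only; flatten list-valued attributes
    for _, data in g.nodes(data=True):
        for k, v in list(data.items()):
            if isinstance(v, (list, tuple)):
                data[k] = ",".join(str(x) for x in v)
    nx.write_graphml(g, path)


def read_graphml(path) -> PhysioNetwork:
    g = nx.read_graphml(path)
    alpha = float(g.graph.get("alpha", 1.0))
    return PhysioNetwork(g, alpha=alpha)


def write_membership_csv(memberships: Dict, path) -> None:
    """memberships: {node: {"community": c, "subcommunity": s (optional)}}."""
    rows = []
    for node, rec in sorted(memberships.items(), key=lambda kv: str(kv[0])):
        row = {"node_id": node}
        row.update(rec)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_scan_csv(scan: ThresholdScanResult, path) -> None:
    scan.records.to_csv(path, index=False)


def write_attack_csv(curves: Dict[str, AttackCurve], path) -> None:
    """Long format: strategy, step, removed_fraction, loss."""
    rows = []
    for strategy, curve in curves.items():
        for step, (frac, loss) in enumerate(
            zip(curve.removed_fraction, curve.connectivity_loss)
        ):
            rows.append(
                {
                    "strategy": strategy,
                    "step": step,
                    "removed_fraction": frac,
                    "loss": loss,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def write_report_json(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
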