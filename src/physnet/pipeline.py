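"""End-to-end orchestration: cohort -> preprocessing -> correlation ->
threshold selection -> network -> topology, centrality, communities, and
optional attack simulation, with every artifact written to an output
directory and a machine-readable JSON report.

Every stochastic stage draws its own named seed from the single master seed
in the config, so two runs of the same config produce byte-identical reports.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Optional, Sequence

import networkx as nx
import numpy as np
import yaml

from . import centrality as _cent
from . import communities as _comm
from . import correlation as _corr
from . import io as _io
from . import preprocess as _prep
from . import robustness as _rob
from . import topology as _top
from ._graph import PhysioNetwork, as_graph
from .cohort import BlockSpec, CohortSpec, CohortTable, generate_cohort


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed (< 2^31)."""
    return int(
        np.random.SeedSequence([int(master), zlib.crc32(stage.encode())]).generate_state(1)[0]
        % (2**31 - 1)
    )


@dataclass
class RunConfig:
    """Declarative pipeline configuration.

    Exactly one of ``values_csv`` (+ optional ``meta_csv``) or ``simulate``
    must be given. ``seed`` is mandatory: every stochastic stage derives a
    named child seed from it.
    """

    outdir: str
    seed: Optional[int] = None
    values_csv: Optional[str] = None
    meta_csv: Optional[str] = None
    simulate: Optional[dict] = None
    normalize: str = "median-range"  # or "none"
    rout_q: Optional[float] = 0.01  # None disables the screen
    derive: Sequence[str] = ()
    alpha: Optional[float] = None  # fixed threshold; None -> scan + select
    grid: Sequence[float] = _corr.DEFAULT_GRID
    min_connectedness: float = 0.95
    cluster_methods: Sequence[str] = ("louvain", "infomap")
    subcluster: bool = False
    permutation_r: int = 1000
    attack: bool = False
    attack_reps: int = 50
    smallworld_b: int = 100

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("config must set an explicit seed")
        if (self.values_csv is None) == (self.simulate is None):
            raise ValueError("set exactly one of values_csv or simulate")
        if self.normalize not in ("median-range", "none"):
            raise ValueError("normalize must be 'median-range' or 'none'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _cohort_from_config(cfg: RunConfig):
    if cfg.simulate is not None:
        sim = dict(cfg.simulate)
        blocks = [BlockSpec(**b) for b in sim.pop("blocks")]
        sim.setdefault("seed", stage_seed(cfg.seed, "simulate"))
        spec = CohortSpec(blocks=blocks, **sim)
        return generate_cohort(spec)
    table = CohortTable.from_csv(cfg.values_csv, cfg.meta_csv)
    return table, None


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full workflow; write artifacts under cfg.outdir.

    Returns the report dict (also written as report.json). The topology block
    carries the conventional summary-table field names.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)
    log = []
    report: dict = {}

    table, planted = _cohort_from_config(cfg)
    table.to_csv(out / "cohort.csv", out / "variables.csv")
    log.append(f"cohort: {table.n_subjects} subjects x {len(table.variables)} variables")

    if cfg.derive:
        table = _prep.derive_variables(table, list(cfg.derive))
        log.append(f"derived variables appended: {list(cfg.derive)}")
    if cfg.rout_q is not None:
        table, screen = _prep.rout_screen(table, cfg.rout_q)
        screen.flagged.to_csv(out / "rout_flagged.csv", index=False)
        log.append(f"ROUT screen at Q={cfg.rout_q}: {len(screen.flagged)} cells flagged")
        report["rout_flagged_cells"] = len(screen.flagged)
    shapiro = _prep.shapiro_screen(table)
    shapiro.shapiro.to_csv(out / "shapiro.csv", index=False)
    report["shapiro_nonnormal_frac"] = float(
        (shapiro.shapiro["p"] < 0.05).mean()
    )
    if cfg.normalize == "median-range":
        table, _params = _prep.normalize_median_range(table)
        log.append("median-range normalization applied")

    corr = _corr.spearman_matrix(table)
    _io.write_correlation_csv(corr, out / "correlation")

    scan_seed = stage_seed(cfg.seed, "scan")
    if cfg.alpha is None:
        scan = _corr.threshold_scan(
            corr, grid=cfg.grid, cluster_methods=cfg.cluster_methods,
            seed=scan_seed, meta=table.meta,
        )
        _io.write_scan_csv(scan, out / "threshold_scan.csv")
        alpha = _corr.select_threshold(scan, cfg.min_connectedness)
        log.append(f"threshold scan over {list(scan.alphas)}; selected alpha={alpha}")
        report["threshold_scan"] = scan.records.to_dict(orient="records")
    else:
        alpha = float(cfg.alpha)
        log.append(f"fixed alpha={alpha}")
    report["alpha"] = alpha

    net = _corr.build_network(corr, alpha, meta=table.meta)
    _io.write_edge_list(net, out / "edges.csv")
    _io.write_graphml(net, out / "network.graphml")

    summ = _top.summarize(
        net, B=cfg.smallworld_b, seed=stage_seed(cfg.seed, "smallworld"),
        include_centrality=True,
    )
    report["topology"] = summ.table_record()

    ec = _cent.eigencentrality(net)
    fb = _cent.flow_betweenness(net)
    strength = _top.node_strength(net)
    deg = dict(as_graph(net).degree())
    import pandas as pd

    pd.DataFrame(
        {
            "id": list(ec.values.index),
            "eigencentrality": ec.values.to_numpy(),
            "flow_betweenness": fb.values.reindex(ec.values.index).to_numpy(),
            "degree": [deg[u] for u in ec.values.index],
            "strength": strength.reindex(ec.values.index).to_numpy(),
        }
    ).to_csv(out / "centrality.csv", index=False)

    memberships: Dict = {}
    report["clusters"] = {}
    partitions = {}
    for method in cfg.cluster_methods:
        seed = stage_seed(cfg.seed, f"cluster:{method}")
        part = _comm.cluster(net, method=method, seed=seed)
        partitions[method] = part
        report["clusters"][method] = {
            "n_communities": part.n_communities,
            "modularity": part.modularity,
            "codelength": part.codelength,
        }
        for u, c in part.membership.items():
            memberships.setdefault(u, {})[f"community_{method}"] = c
        if cfg.subcluster:
            subs = _comm.subcluster(net, part, method=method, seed=seed)
            for label, sub in subs.items():
                for u, c in sub.membership.items():
                    memberships[u][f"subcommunity_{method}"] = f"{label}.{c}"
        cg = _comm.contract_clusters(net, part)
        _io.write_graphml(PhysioNetwork(cg.simple_projection(), alpha), out / f"clusters_{method}.graphml")
    if len(partitions) >= 2:
        keys = list(partitions)
        report["cluster_agreement"] = {
            "rand": _comm.rand_index(partitions[keys[0]], partitions[keys[1]]),
            "vi": _comm.variation_of_information(partitions[keys[0]], partitions[keys[1]]),
        }
    if planted is not None:
        first = partitions[list(partitions)[0]]
        report["planted_adjusted_rand"] = _comm.adjusted_rand_index(first, planted)
    _io.write_membership_csv(memberships, out / "memberships.csv")

    if cfg.attack:
        curves = _rob.attack_suite(
            net, reps=cfg.attack_reps, seed=stage_seed(cfg.seed, "attack")
        )
        _io.write_attack_csv(curves, out / "attack.csv")
        report["attack_auc"] = {s: c.auc for s, c in curves.items()}

    report["log"] = log
    _io.write_report_json(report, out / "report.json")
    return report


@dataclass
class LayoutCoordinates:
    coordinates: Dict  # node -> (x, y)
    algorithm: str
    seed: Optional[int]


def merged_layout(net1, net2, seed: int | None = None) -> LayoutCoordinates:
    """Fruchterman–Reingold layout of the union of both edge lists.

    Shared nodes get identical coordinates in both renderings because both
    networks reuse the one merged layout.
    """
    merged = nx.compose(as_graph(net1), as_graph(net2))
    pos = nx.spring_layout(merged, seed=seed)
    coords = {u: (float(x), float(y)) for u, (x, y) in pos.items()}
    return LayoutCoordinates(coords, "fruchterman_reingold", seed)
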