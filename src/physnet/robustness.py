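"""Attack-tolerance simulation: connectivity loss under node removal.

Connectivity loss after removing a node set is 1 minus the ratio of still-
connected unordered pairs among survivors to connected pairs in the intact
network. Four removal strategies are simulated: uniformly random failure
(averaged over repetitions), static degree-ranked attack, static
betweenness-ranked attack, and a cascading attack that recomputes shortest-
path betweenness after every removal and always removes the current maximum.
Betweenness is unweighted (binary structure), the robustness-literature
default. Ties break by ascending node id, making deterministic curves
bit-for-bit reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._graph import as_graph, node_order, to_igraph

STRATEGIES = ("random", "degree", "betweenness", "cascading")


@dataclass
class AttackCurve:
    strategy: str
    removed_fraction: np.ndarray  # length n+1, starts at 0
    connectivity_loss: np.ndarray  # loss(0) = 0, loss(1) = 1
    reps: Optional[int] = None  # random strategy only
    seed: Optional[int] = None

    @property
    def auc(self) -> float:
        """Area under the loss curve; higher = more fragile."""
        return float(np.trapezoid(self.connectivity_loss, self.removed_fraction))


def _connected_pairs(h) -> int:
    return sum(s * (s - 1) // 2 for s in h.connected_components().sizes())


def connectivity_loss(net, removed) -> float:
    """1 - (connected surviving pairs) / (connected intact pairs)."""
    g = as_graph(net)
    removed = set(removed)
    unknown = removed - set(g.nodes)
    if unknown:
        raise ValueError(f"unknown node(s): {sorted(unknown, key=str)}")
    h, nodes = to_igraph(g, weight=None)
    base = _connected_pairs(h)
    if base == 0:
        return 0.0 if len(removed) < len(nodes) else 1.0
    keep = [i for i, u in enumerate(nodes) if u not in removed]
    if not keep:
        return 1.0
    return 1.0 - _connected_pairs(h.induced_subgraph(keep)) / base


def _loss_along_sequence(h, order: Sequence[int], base: int) -> np.ndarray:
    """Loss after each removal for a fixed full removal order (vertex ids)."""
    n = h.vcount()
    losses = np.empty(n + 1)
    losses[0] = 0.0
    alive = np.ones(n, dtype=bool)
    for step, vid in enumerate(order, start=1):
        alive[vid] = False
        keep = np.flatnonzero(alive).tolist()
        losses[step] = 1.0 - _connected_pairs(h.induced_subgraph(keep)) / base
    return losses


def attack(
    net,
    strategy: str,
    reps: int = 50,
    seed: int | None = None,
) -> AttackCurve:
    """Remove all nodes in the order given by ``strategy``; record the curve.

    random: curve averaged over ``reps`` uniformly random sequences.
    degree / betweenness: static descending initial ranking.
    cascading: recompute betweenness on the surviving graph at every step.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    g = as_graph(net)
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("attack needs at least 2 nodes")
    h, nodes = to_igraph(g, weight=None)
    base = _connected_pairs(h)
    if base == 0:
        raise ValueError("intact network has no connected pairs")
    fractions = np.arange(n + 1) / n

    if strategy == "random":
        rng = np.random.default_rng(seed)
        acc = np.zeros(n + 1)
        for _ in range(reps):
            order = rng.permutation(n)
            acc += _loss_along_sequence(h, order, base)
        return AttackCurve(strategy, fractions, acc / reps, reps=reps, seed=seed)

    if strategy in ("degree", "betweenness"):
        if strategy == "degree":
            scores = np.asarray(h.degree(), dtype=float)
        else:
            scores = np.asarray(h.betweenness(), dtype=float)
        order = sorted(range(n), key=lambda i: (-scores[i], str(nodes[i])))
        losses = _loss_along_sequence(h, order, base)
        return AttackCurve(strategy, fractions, losses, seed=seed)

    # cascading: recompute betweenness after every removal
    losses = np.empty(n + 1)
    losses[0] = 0.0
    alive = np.ones(n, dtype=bool)
    for step in range(1, n + 1):
        keep = np.flatnonzero(alive).tolist()
        sub = h.induced_subgraph(keep)
        scores = np.asarray(sub.betweenness(), dtype=float)
        local = sorted(
            range(len(keep)), key=lambda i: (-scores[i], str(nodes[keep[i]]))
        )[0]
        alive[keep[local]] = False
        keep = np.flatnonzero(alive).tolist()
        losses[step] = 1.0 - _connected_pairs(h.induced_subgraph(keep)) / base
    return AttackCurve("cascading", fractions, losses, seed=seed)


def attack_suite(net, reps: int = 50, seed: int | None = None) -> dict:
    """All four attack curves keyed by strategy."""
    return {s: attack(net, s, reps=reps, seed=seed) for s in STRATEGIES}
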