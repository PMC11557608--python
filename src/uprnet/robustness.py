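"""Network robustness under random and metric-targeted node removal.

Nodes are ranked once on the intact network by a chosen descriptor and
removed in order; after each removal the trace records the largest-
connected-component fraction G_i = n_i / N and the efficiency drop
dE_i = (E - E_i) / E.  The robustness index R is the mean of G_i over the
full removal sequence; jumps flag single removals that collapse the LCC by
at least a threshold fraction of the network.

E_i keeps the intact network's N(N-1) pair count as denominator, with
removed or mutually unreachable pairs contributing zero, so the drop is
non-decreasing along any removal order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from uprnet import descriptors

__all__ = [
    "AttackTrace",
    "attack_order",
    "run_attack",
    "robustness_R",
    "detect_jumps",
]

_STRATEGIES = ("random", "degree", "closeness", "betweenness")


@dataclass
class AttackTrace:
    """Removal order with the LCC and efficiency degradation sequences."""

    order: list
    lcc_sizes: list[int]          # n_i, exact integer LCC node counts
    lcc_fraction: list[float]     # G_i = n_i / N
    efficiency_drop: list[float]  # dE_i = (E - E_i) / E
    n_nodes: int
    initial_lcc_size: int
    initial_efficiency: float
    strategy: str = "custom"
    direction: str = "ascending"


def attack_order(
    net: nx.Graph,
    strategy: str,
    direction: str = "ascending",
    seed: int = 0,
) -> list:
    """Node removal order by a static descriptor of the intact network.

    ``ascending`` removes the least "important" nodes first (the published
    convention); ties break lexicographically by node id.  ``random`` is a
    seeded shuffle, unaffected by direction.
    """
    if strategy not in _STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {_STRATEGIES}")
    if direction not in ("ascending", "descending"):
        raise ValueError("direction must be 'ascending' or 'descending'")
    nodes = sorted(net.nodes(), key=str)
    if strategy == "random":
        rng = np.random.default_rng(seed)
        return [nodes[i] for i in rng.permutation(len(nodes))]
    table = descriptors.node_metrics(net).nodes
    key = {"degree": "degree", "closeness": "closeness", "betweenness": "betweenness"}[strategy]
    reverse = direction == "descending"
    return sorted(nodes, key=lambda v: ((-table.at[v, key]) if reverse else table.at[v, key], str(v)))


def _global_efficiency_sum(net: nx.Graph) -> float:
    """Sum of 1/d over ordered reachable pairs of the current graph."""
    total = 0.0
    for v in net.nodes():
        for u, d in nx.single_source_shortest_path_length(net, v).items():
            if d > 0:
                total += 1.0 / d
    return total


def run_attack(net: nx.Graph, order: Sequence, efficiency: bool = True) -> AttackTrace:
    """Execute a full removal sequence and record the degradation trace.

    ``efficiency=False`` skips the all-pairs efficiency recomputation (the
    expensive part on larger networks) and records an empty drop sequence.
    """
    nodes = set(net.nodes())
    if len(order) != len(nodes) or set(order) != nodes:
        raise ValueError("order must be a permutation of the node set")
    n = len(nodes)
    g = net.copy()
    denom = n * (n - 1) if n > 1 else 1
    e0 = _global_efficiency_sum(g) / denom if efficiency else 0.0
    lcc0 = max((len(c) for c in nx.connected_components(g)), default=0)
    sizes, drops = [], []
    for v in order:
        g.remove_node(v)
        lcc = max((len(c) for c in nx.connected_components(g)), default=0)
        sizes.append(lcc)
        if efficiency:
            ei = _global_efficiency_sum(g) / denom
            drops.append((e0 - ei) / e0 if e0 > 0 else 0.0)
    return AttackTrace(
        order=list(order),
        lcc_sizes=sizes,
        lcc_fraction=[s / n for s in sizes],
        efficiency_drop=drops,
        n_nodes=n,
        initial_lcc_size=lcc0,
        initial_efficiency=e0,
    )


def robustness_R(trace: AttackTrace) -> float:
    """Robustness index R = N^-1 sum_i G_i over the full removal sequence."""
    return float(sum(trace.lcc_fraction) / trace.n_nodes)


def detect_jumps(
    trace: AttackTrace, threshold: float = 0.10, strict: bool = False,
) -> list[tuple[int, object, float]]:
    """Removals that collapse the LCC by at least ``threshold`` of N.

    Returns ``(step, removed_node, delta_G)`` tuples (1-based steps); the
    pre-attack LCC fraction serves as G_0.  The comparison is inclusive
    (>=, "at least"), evaluated in exact rational arithmetic so a drop of
    exactly the threshold is flagged; ``strict=True`` switches to >.
    """
    n = trace.n_nodes
    thr = Fraction(str(threshold))
    prev = trace.initial_lcc_size
    jumps = []
    for i, (node, size) in enumerate(zip(trace.order, trace.lcc_sizes), start=1):
        drop = Fraction(prev - size, n)
        hit = drop > thr if strict else drop >= thr
        if hit:
            jumps.append((i, node, float(drop)))
        prev = size
    return jumps
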