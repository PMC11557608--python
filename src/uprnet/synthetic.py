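"""Seeded synthetic networks with the statistical structure of curated PPI maps.

Real UPR interaction networks are small (tens to low hundreds of proteins),
dense for curated pathways, dominated by a chaperone hub (the BiP/HSPA5
barycenter role), heavy-tailed in degree, and organized into a handful of
communities.  This module generates graphs with exactly those coarse
features so every downstream stage (descriptors, null models, GHD,
robustness, controllability) is testable without database downloads.

All generators are driven by a single integer seed through a private
``numpy.random.Generator``; identical calls are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from uprnet import organisms

__all__ = [
    "SyntheticProfile",
    "canonical_graph",
    "realize_degree_sequence",
    "sample_graphical_network",
    "emulate_organism",
]


@dataclass
class SyntheticProfile:
    """Parameters for a synthetic network draw.

    Exactly one of ``degree_sequence`` (realized exactly) or the planted
    community parameters (``n_communities``/``p_in``/``p_out``) drives the
    topology; when neither is given a heavy-tailed sequence with exponent
    ``powerlaw_exponent`` and an optional dominant hub is sampled.
    """

    n_nodes: int
    degree_sequence: Optional[Sequence[int]] = None
    powerlaw_exponent: float = 2.0
    hub_degree: Optional[int] = None
    n_communities: Optional[int] = None
    community_sizes: Optional[Sequence[int]] = None
    p_in: float = 0.9
    p_out: float = 0.05
    seed: int = 0
    node_labels: Optional[Sequence[str]] = field(default=None, repr=False)

    def __post_init__(self):
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        for p, nm in [(self.p_in, "p_in"), (self.p_out, "p_out")]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{nm} must be in [0, 1], got {p}")
        if self.degree_sequence is not None:
            seq = list(self.degree_sequence)
            if len(seq) != self.n_nodes:
                raise ValueError("degree_sequence length must equal n_nodes")
            _check_graphical(seq)


def _check_graphical(seq: Sequence[int]) -> None:
    """Raise with the violated Erdős–Gallai inequality (or parity) if not graphical."""
    seq = sorted((int(d) for d in seq), reverse=True)
    n = len(seq)
    if any(d < 0 for d in seq):
        raise ValueError("degree sequence has negative entries")
    if seq and seq[0] > n - 1:
        raise ValueError(f"max degree {seq[0]} exceeds n-1 = {n - 1}")
    if sum(seq) % 2 != 0:
        raise ValueError(f"degree sum {sum(seq)} is odd (no graph realizes it)")
    prefix = 0
    for k in range(1, n + 1):
        prefix += seq[k - 1]
        bound = k * (k - 1) + sum(min(d, k) for d in seq[k:])
        if prefix > bound:
            raise ValueError(
                "Erdős–Gallai violation at k="
                f"{k}: sum of top {k} degrees {prefix} > {bound}"
            )


def canonical_graph(kind: str, n: int) -> nx.Graph:
    """Deterministic named graphs (labels ``v1..vn``) used as analytic oracles.

    Kinds: ``star``, ``path``, ``cycle``, ``complete``, ``two_clique_bridge``
    (two K_{n/2} blocks joined by a single bridge edge), ``empty``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    labels = [f"v{i}" for i in range(1, n + 1)]
    g = nx.Graph()
    g.add_nodes_from(labels)
    if kind == "star":
        g.add_edges_from((labels[0], v) for v in labels[1:])
    elif kind == "path":
        g.add_edges_from(zip(labels, labels[1:]))
    elif kind == "cycle":
        if n < 3:
            raise ValueError("cycle needs n >= 3")
        g.add_edges_from(zip(labels, labels[1:] + labels[:1]))
    elif kind == "complete":
        g.add_edges_from(
            (labels[i], labels[j]) for i in range(n) for j in range(i + 1, n)
        )
    elif kind == "two_clique_bridge":
        if n < 4 or n % 2:
            raise ValueError("two_clique_bridge needs even n >= 4")
        half = n // 2
        for block in (labels[:half], labels[half:]):
            g.add_edges_from(
                (block[i], block[j]) for i in range(half) for j in range(i + 1, half)
            )
        g.add_edge(labels[half - 1], labels[half])
    elif kind == "empty":
        pass
    else:
        raise ValueError(f"unknown canonical graph kind {kind!r}")
    return g


def realize_degree_sequence(
    nodes: Sequence, degrees: Sequence[int], rng: np.random.Generator,
    stub_attempts: int = 40,
) -> nx.Graph:
    """Random simple graph realizing ``degrees`` on ``nodes`` exactly.

    Random stub matching with rejection of self-loops/multi-edges is tried
    first; if no clean pairing appears within ``stub_attempts`` shuffles the
    sequence is realized deterministically (Havel–Hakimi) and randomized by
    seeded double-edge swaps, which preserve the degree sequence exactly.
    """
    if len(nodes) != len(degrees):
        raise ValueError("nodes and degrees must have equal length")
    _check_graphical(degrees)
    nodes = list(nodes)
    stubs = np.repeat(np.arange(len(nodes)), degrees)
    m = len(stubs) // 2
    for _ in range(stub_attempts):
        perm = rng.permutation(stubs)
        pairs = {(min(a, b), max(a, b)) for a, b in zip(perm[:m], perm[m:])}
        if len(pairs) == m and all(a != b for a, b in pairs):
            g = nx.Graph()
            g.add_nodes_from(nodes)
            g.add_edges_from((nodes[a], nodes[b]) for a, b in pairs)
            return g
    g = _havel_hakimi(list(degrees))
    if g.number_of_edges() >= 2 and g.number_of_nodes() >= 4:
        nswap = max(4 * g.number_of_edges(), 32)
        try:
            nx.double_edge_swap(
                g, nswap=nswap, max_tries=100 * nswap,
                seed=int(rng.integers(2**31)),
            )
        except nx.NetworkXException:
            pass  # sequences with a unique realization reject every swap
    return nx.relabel_nodes(g, dict(enumerate(nodes)))


def _havel_hakimi(degrees: list[int]) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(len(degrees)))
    remaining = [(d, i) for i, d in enumerate(degrees)]
    while True:
        remaining.sort(reverse=True)
        d, v = remaining[0]
        if d == 0:
            return g
        if d > len(remaining) - 1:
            raise ValueError("non-graphical sequence reached in Havel–Hakimi")
        remaining[0] = (0, v)
        for k in range(1, d + 1):
            dk, u = remaining[k]
            if dk == 0:
                raise ValueError("non-graphical sequence reached in Havel–Hakimi")
            g.add_edge(v, u)
            remaining[k] = (dk - 1, u)


def sample_graphical_network(profile: SyntheticProfile) -> nx.Graph:
    """Sample a simple undirected graph from a :class:`SyntheticProfile`.

    Explicit degree sequences are realized exactly; planted-community
    profiles draw independent Bernoulli edges with probability ``p_in``
    within blocks and ``p_out`` between; otherwise a heavy-tailed sequence
    is sampled and realized.  Planted block memberships are stored in the
    ``"block"`` node attribute.
    """
    rng = np.random.default_rng(profile.seed)
    n = profile.n_nodes
    labels = list(profile.node_labels) if profile.node_labels else [
        f"v{i}" for i in range(1, n + 1)
    ]
    if profile.degree_sequence is not None:
        return realize_degree_sequence(labels, list(profile.degree_sequence), rng)
    if profile.n_communities is not None or profile.community_sizes is not None:
        sizes = list(profile.community_sizes) if profile.community_sizes else None
        if sizes is None:
            k = profile.n_communities
            base, extra = divmod(n, k)
            sizes = [base + (1 if i < extra else 0) for i in range(k)]
        if sum(sizes) != n:
            raise ValueError("community sizes must sum to n_nodes")
        g = nx.Graph()
        block_of = {}
        idx = 0
        for b, size in enumerate(sizes):
            for _ in range(size):
                g.add_node(labels[idx], block=b)
                block_of[labels[idx]] = b
                idx += 1
        names = list(g.nodes())
        for i in range(n):
            for j in range(i + 1, n):
                p = profile.p_in if block_of[names[i]] == block_of[names[j]] else profile.p_out
                if rng.random() < p:
                    g.add_edge(names[i], names[j])
        return g
    seq = _heavy_tailed_sequence(
        n, rng, exponent=profile.powerlaw_exponent, hub_degree=profile.hub_degree
    )
    return realize_degree_sequence(labels, seq, rng)


def _heavy_tailed_sequence(
    n: int,
    rng: np.random.Generator,
    exponent: float = 2.0,
    hub_degree: Optional[int] = None,
    target_sum: Optional[int] = None,
) -> list[int]:
    """Graphical heavy-tailed degree sequence; index 0 carries the hub.

    When ``target_sum`` is given the sequence is adjusted to sum to it
    exactly (so node and edge counts can be pinned); minimum degree is 1 so
    the graph has no isolates.
    """
    if n == 1:
        return [0]
    max_deg = n - 1
    hub = hub_degree if hub_degree is not None else max(2, round(0.75 * max_deg))
    hub = min(hub, max_deg)
    # Pareto-like tail for the non-hub nodes, clipped below the hub.
    raw = (1.0 - rng.random(n - 1)) ** (-1.0 / (exponent - 1.0))
    raw = np.clip(raw, 1.0, None)
    if target_sum is not None:
        rest_target = target_sum - hub
        scale = rest_target / raw.sum()
        seq = np.clip(np.rint(raw * scale), 1, max(hub - 1, 1)).astype(int)
    else:
        seq = np.clip(np.rint(raw), 1, max(hub - 1, 1)).astype(int)
    seq = [hub] + seq.tolist()
    want = target_sum if target_sum is not None else None
    if want is None and sum(seq) % 2:
        seq[-1] += 1 if seq[-1] < hub - 1 else -1
    else:
        seq = _adjust_sum(seq, want, lo=1, hi=max(hub - 1, 1)) if want else seq
    # Repair toward graphicality: shave the largest non-hub degrees.
    for _ in range(10 * n):
        try:
            _check_graphical(seq)
            return seq
        except ValueError:
            order = sorted(range(1, len(seq)), key=lambda i: -seq[i])
            hi_i, lo_i = order[0], order[-1]
            if seq[hi_i] <= 1 or seq[lo_i] >= max(hub - 1, 1):
                raise
            seq[hi_i] -= 1
            seq[lo_i] += 1
    raise ValueError("could not repair degree sequence to graphicality")


def _adjust_sum(seq: list[int], target: int, lo: int, hi: int) -> list[int]:
    """Nudge non-hub entries (index >= 1) within [lo, hi] until sum == target."""
    seq = list(seq)
    i = 1
    guard = 0
    while sum(seq) != target:
        step = 1 if sum(seq) < target else -1
        j = 1 + (i - 1) % (len(seq) - 1)
        cand = seq[j] + step
        if lo <= cand <= hi:
            seq[j] = cand
        i += 1
        guard += 1
        if guard > 10000 * len(seq):
            raise ValueError(f"cannot reach degree sum {target} within bounds")
    return seq


def emulate_organism(name: str, seed: int = 0) -> nx.Graph:
    """Synthetic stand-in for a published organism UPR network.

    Matches the organism's printed node count and directed edge-record
    count exactly (hence its printed density), labels the dominant hub with
    the organism's barycenter protein, and draws the remaining degrees from
    a heavy-tailed distribution.  Finer STRING topology (exact communities,
    clustering) is not emulated.
    """
    prof = organisms.lookup(name)
    rng = np.random.default_rng(seed)
    n = prof.n_nodes
    labels = [prof.hub_label] + [f"{prof.hub_label.upper()[:3]}_P{i:03d}" for i in range(1, n)]
    hub = min(n - 1, max(round(0.75 * (n - 1)), int(np.ceil(2 * prof.n_edges * 2 / n))))
    hub = min(hub, n - 1)
    seq = _heavy_tailed_sequence(
        n, rng, exponent=2.0, hub_degree=hub, target_sum=2 * prof.n_edges
    )
    g = realize_degree_sequence(labels, seq, rng)
    g.graph["organism"] = prof.name
    g.graph["barycenter_label"] = prof.hub_label
    return g
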