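"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the code paths they check: distances come
from a hand-rolled BFS, betweenness from explicit shortest-path
enumeration, minimum driver counts from exhaustive subset search with a
numeric generic-weight Kalman rank, and modularity optima from exhaustive
set-partition search.
"""

from __future__ import annotations

import itertools
from collections import deque

import networkx as nx
import numpy as np
import pytest


# ---------------------------------------------------------------------------
# Random graph corpus (exactly the study sizes used by the oracle suites)


def small_graph_corpus(n_graphs: int = 100, max_n: int = 8, directed_half: bool = True):
    """Seeded corpus of random graphs with 2..max_n nodes.

    Even indices are undirected G(n, p), odd indices directed G(n, p) when
    ``directed_half``; p sweeps sparse to dense so disconnected graphs,
    trees and near-cliques all occur.
    """
    graphs = []
    for i in range(n_graphs):
        rng = np.random.default_rng(20_000 + i)
        n = int(rng.integers(2, max_n + 1))
        p = float(rng.uniform(0.1, 0.8))
        directed = directed_half and (i % 2 == 1)
        g = nx.DiGraph() if directed else nx.Graph()
        g.add_nodes_from(range(n))
        for u in range(n):
            for v in range(n):
                if u == v or (not directed and u > v):
                    continue
                if rng.random() < p:
                    g.add_edge(u, v)
        graphs.append(g)
    return graphs


@pytest.fixture(scope="session")
def graph_corpus():
    return small_graph_corpus()


@pytest.fixture(scope="session")
def undirected_corpus(graph_corpus):
    return [g for g in graph_corpus if not g.is_directed()]


# ---------------------------------------------------------------------------
# Descriptor oracles


def bfs_distances(net: nx.Graph, source):
    dist = {source: 0}
    q = deque([source])
    while q:
        v = q.popleft()
        for u in net.neighbors(v):
            if u not in dist:
                dist[u] = dist[v] + 1
                q.append(u)
    return dist


def brute_closeness(net: nx.Graph, v) -> float:
    total = sum(bfs_distances(net, v).values())
    return 1.0 / total if total > 0 else 0.0


def _all_shortest_paths(net: nx.Graph, s, t, dist):
    """Explicit enumeration of shortest s-t paths by distance-decreasing walk."""
    if t not in dist:
        return []
    paths = []

    def back(v, acc):
        if v == s:
            paths.append([s] + acc)
            return
        for u in net.neighbors(v):
            if u in dist and dist[u] == dist[v] - 1:
                back(u, [v] + acc)

    back(t, [])
    return paths


def brute_betweenness(net: nx.Graph, v) -> float:
    """Unordered-pair shortest-path count fraction through v."""
    total = 0.0
    nodes = sorted(net.nodes(), key=str)
    for i, s in enumerate(nodes):
        dist = bfs_distances(net, s)
        for t in nodes[i + 1:]:
            if s == v or t == v or t not in dist:
                continue
            paths = _all_shortest_paths(net, s, t, dist)
            if paths:
                through = sum(1 for p in paths if v in p)
                total += through / len(paths)
    return total


def brute_clustering(net: nx.Graph, v) -> float:
    nbrs = list(net.neighbors(v))
    k = len(nbrs)
    if k < 2:
        return 0.0
    links = sum(
        1 for a, b in itertools.combinations(nbrs, 2) if net.has_edge(a, b)
    )
    return links / (k * (k - 1) / 2)


# ---------------------------------------------------------------------------
# Controllability oracle: exhaustive subset search with numeric generic Kalman


def _generic_A(net, rng) -> tuple[np.ndarray, list]:
    D = net if net.is_directed() else net.to_directed()
    nodes = sorted(D.nodes(), key=str)
    idx = {v: i for i, v in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)))
    for u, v in D.edges():
        w = rng.uniform(0.5, 1.5) * (1 if rng.random() < 0.5 else -1)
        A[idx[v], idx[u]] = w
    return A, nodes


def _numeric_controllable(A: np.ndarray, cols: list[int]) -> bool:
    n = A.shape[0]
    B = np.zeros((n, len(cols)))
    for j, c in enumerate(cols):
        B[c, j] = 1.0
    blocks = [B]
    X = B
    for _ in range(n - 1):
        X = A @ X
        blocks.append(X)
    return int(np.linalg.matrix_rank(np.hstack(blocks))) == n


def brute_min_driver_count(net, seed: int = 0) -> int:
    """Smallest k such that some k-subset of dedicated inputs makes the
    generic-weight system controllable; two weight draws guard against a
    non-generic draw."""
    n = net.number_of_nodes()
    rngs = [np.random.default_rng(seed + 7 * r) for r in range(2)]
    mats = [_generic_A(net, rng)[0] for rng in rngs]
    for k in range(1, n + 1):
        for cols in itertools.combinations(range(n), k):
            if any(_numeric_controllable(A, list(cols)) for A in mats):
                return k
    return n


# ---------------------------------------------------------------------------
# Modularity oracle: exhaustive search over set partitions


def _set_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def best_partition_exhaustive(net: nx.Graph):
    """Globally modularity-optimal partition by exhaustive enumeration."""
    nodes = sorted(net.nodes(), key=str)
    m = net.number_of_edges()
    deg = dict(net.degree())
    best_q, best_p = -np.inf, None
    for part in _set_partitions(nodes):
        q = 0.0
        for block in part:
            bs = set(block)
            intra = sum(1 for a, b in net.edges(bs) if a in bs and b in bs)
            dsum = sum(deg[v] for v in block)
            q += intra / m - (dsum / (2 * m)) ** 2
        if q > best_q:
            best_q, best_p = q, part
    return best_q, [set(b) for b in best_p]
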