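"""Standard descriptor suite for PPI networks.

Per-node: degree, raw closeness C(x) = (sum_y d(x,y))^-1, unnormalized
betweenness (shortest-path pair counts, the scale on which curated PPI
networks show values of order 10-180), local clustering, eccentricity.
Per-network: density, diameter, barycenter (minimum-eccentricity node),
average path length, global efficiency, Louvain communities and modularity.
Normalized variants remove the dependence on network size: degree/(N-1),
(N-1)*closeness, min-max betweenness.

Distance-based aggregates on disconnected networks are computed on the
largest connected component with a logged warning, since raw closeness and
path-length sums are undefined across components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "MetricTable",
    "density",
    "node_metrics",
    "network_aggregates",
    "normalize",
    "detect_communities",
    "metric_report_row",
]


@dataclass
class MetricTable:
    """Per-node descriptors plus (optionally filled) network aggregates.

    ``nodes`` columns: degree, closeness, betweenness, clustering,
    eccentricity, and after :func:`normalize` also norm_degree,
    norm_closeness, norm_betweenness.
    """

    nodes: pd.DataFrame
    n_nodes: int
    n_edges: int
    density: Optional[float] = None
    diameter: Optional[int] = None
    barycenter: Optional[str] = None
    avg_degree: Optional[float] = None
    avg_closeness: Optional[float] = None
    avg_betweenness: Optional[float] = None
    avg_clustering: Optional[float] = None
    avg_path_length: Optional[float] = None
    efficiency: Optional[float] = None
    modularity: Optional[float] = None
    communities: Optional[list[set]] = field(default=None, repr=False)
    n_communities: Optional[int] = None
    connected: bool = True


def density(n: int, m: int) -> float:
    """Edge density 2M / (N (N-1)) of an N-node, M-undirected-edge network.

    Equals (directed records) / (N (N-1)) under the STRING two-records-
    per-interaction convention.
    """
    if n < 2:
        return 0.0
    return 2.0 * m / (n * (n - 1))


def _distances_within_component(net: nx.Graph, source) -> dict:
    return nx.single_source_shortest_path_length(net, source)


def node_metrics(net: nx.Graph) -> MetricTable:
    """Compute the per-node descriptor suite.

    Closeness is the raw reciprocal distance sum restricted to the node's
    connected component (not the size-rescaled variant); betweenness is the
    raw shortest-path pair count (unordered pairs); clustering is 0 for
    degree < 2.
    """
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("network has no nodes")
    nodes = sorted(net.nodes(), key=str)
    degree = dict(net.degree())
    clustering = nx.clustering(net)
    betweenness = nx.betweenness_centrality(net, normalized=False)
    closeness, eccentricity, dist_sum = {}, {}, {}
    for v in nodes:
        dists = _distances_within_component(net, v)
        total = sum(dists.values())
        dist_sum[v] = total
        closeness[v] = 1.0 / total if total > 0 else 0.0
        eccentricity[v] = max(dists.values()) if dists else 0
    df = pd.DataFrame(
        {
            "degree": [degree[v] for v in nodes],
            "closeness": [closeness[v] for v in nodes],
            "betweenness": [betweenness[v] for v in nodes],
            "clustering": [clustering[v] for v in nodes],
            "eccentricity": [eccentricity[v] for v in nodes],
            "_dist_sum": [dist_sum[v] for v in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )
    return MetricTable(nodes=df, n_nodes=n, n_edges=net.number_of_edges(),
                       connected=(n == 1 or nx.is_connected(net)))


def network_aggregates(net: nx.Graph, table: Optional[MetricTable] = None) -> MetricTable:
    """Fill the network-level aggregates of a :class:`MetricTable`.

    Averages are arithmetic means over all nodes; density is 2M/(N(N-1));
    diameter/barycenter/average path length/efficiency come from shortest
    paths, computed on the largest connected component (with a warning)
    when the network is disconnected.  Barycenter ties break by lower total
    distance, then lexicographic node id.
    """
    if table is None:
        table = node_metrics(net)
    t = table
    df = t.nodes
    n = t.n_nodes
    t.density = density(n, t.n_edges)
    t.avg_degree = float(df["degree"].mean())
    t.avg_closeness = float(df["closeness"].mean())
    t.avg_betweenness = float(df["betweenness"].mean())
    t.avg_clustering = float(df["clustering"].mean())

    if t.connected:
        comp_nodes = list(df.index)
    else:
        comp_nodes = sorted(max(nx.connected_components(net), key=len), key=str)
        log.warning(
            "network is disconnected; distance-based aggregates computed on "
            "the %d-node largest connected component", len(comp_nodes),
        )
    sub = df.loc[comp_nodes]
    t.diameter = int(sub["eccentricity"].max()) if len(comp_nodes) > 1 else 0
    # barycenter: min eccentricity, ties by total distance then node id
    order = sorted(
        comp_nodes,
        key=lambda v: (df.at[v, "eccentricity"], df.at[v, "_dist_sum"], str(v)),
    )
    t.barycenter = order[0]
    nc = len(comp_nodes)
    if nc > 1:
        comp = net.subgraph(comp_nodes)
        total_d = 0
        total_inv = 0.0
        for v in comp_nodes:
            dists = _distances_within_component(comp, v)
            for u, d in dists.items():
                if u == v:
                    continue
                total_d += d
                total_inv += 1.0 / d
        denom = nc * (nc - 1)
        t.avg_path_length = total_d / denom
        t.efficiency = total_inv / denom
    else:
        t.avg_path_length = 0.0
        t.efficiency = 0.0
    return t


def normalize(table: MetricTable, n: Optional[int] = None) -> MetricTable:
    """Fill size-independent normalized descriptors.

    norm_degree = k/(N-1); norm_closeness = (N-1)*C; norm_betweenness is
    min-max scaled (identically 0 when all betweenness values coincide).
    """
    if n is None:
        n = table.n_nodes
    if n < 2:
        raise ValueError("normalization needs N >= 2")
    df = table.nodes
    df["norm_degree"] = df["degree"] / (n - 1)
    df["norm_closeness"] = (n - 1) * df["closeness"]
    bmin, bmax = df["betweenness"].min(), df["betweenness"].max()
    if bmax > bmin:
        df["norm_betweenness"] = (df["betweenness"] - bmin) / (bmax - bmin)
    else:
        df["norm_betweenness"] = 0.0
    return table


def detect_communities(net: nx.Graph, seed: int = 0):
    """Louvain partition of the network.

    Returns ``(partition, modularity, n_communities)`` where partition is a
    list of node sets covering the network disjointly.  Resolution is fixed
    at 1.0; the seed controls node traversal order.  An edgeless network
    yields singleton communities with Q = 0.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("network has no nodes")
    if net.number_of_edges() == 0:
        parts = [{v} for v in sorted(net.nodes(), key=str)]
        return parts, 0.0, len(parts)
    parts = nx.community.louvain_communities(net, resolution=1.0, seed=seed)
    parts = sorted((set(p) for p in parts), key=lambda p: sorted(map(str, p)))
    q = nx.community.modularity(net, parts)
    return parts, float(q), len(parts)


def metric_report_row(name: str, table: MetricTable) -> dict:
    """One report row per network, mirroring the published summary layout."""
    return {
        "organism": name,
        "barycenter": table.barycenter,
        "n_nodes": table.n_nodes,
        "edge_records": 2 * table.n_edges,
        "density": table.density,
        "diameter": table.diameter,
        "avg_degree": table.avg_degree,
        "avg_closeness": table.avg_closeness,
        "avg_betweenness": table.avg_betweenness,
        "avg_clustering": table.avg_clustering,
        "modularity": table.modularity,
        "n_communities": table.n_communities,
    }
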