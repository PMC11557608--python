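"""Degree-preserving null ensembles and the statistical battery.

Configuration-model replicates preserve every node's degree exactly while
shuffling connections; z-scores locate a native network's aggregate
descriptors within the replicate distribution.  Non-parametric tests
(Wilcoxon signed-rank for paired native-vs-null node distributions,
Kruskal-Wallis with Bonferroni correction across organisms), Pearson
correlation, and hierarchical (UPGMA) clustering complete the battery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import linkage

from uprnet import descriptors
from uprnet.synthetic import realize_degree_sequence

__all__ = [
    "NullEnsemble",
    "ZScore",
    "configuration_model",
    "build_ensemble",
    "zscore",
    "ensemble_zscores",
    "paired_signed_rank",
    "cross_species_test",
    "pearson",
    "hierarchical_dendrogram",
]


@dataclass
class ZScore:
    """z = (x - mu) / sigma of a native aggregate against its null ensemble."""

    value: Optional[float]
    native: float
    mean: float
    std: float

    @property
    def defined(self) -> bool:
        return self.value is not None


@dataclass
class NullEnsemble:
    """A native network with R degree-preserving randomizations."""

    native: nx.Graph
    replicates: list[nx.Graph]
    tables: list[descriptors.MetricTable]

    @property
    def R(self) -> int:
        return len(self.replicates)


def configuration_model(net: nx.Graph, seed: int = 0) -> nx.Graph:
    """One simple-graph configuration-model replicate.

    Same node set, identical per-node degree, connections randomized (stub
    matching with rejection, falling back to Havel-Hakimi + double-edge-swap
    mixing).  Deterministic for a given seed.
    """
    nodes = sorted(net.nodes(), key=str)
    degrees = [net.degree(v) for v in nodes]
    rng = np.random.default_rng(seed)
    return realize_degree_sequence(nodes, degrees, rng)


def build_ensemble(net: nx.Graph, R: int = 10, seed: int = 0) -> NullEnsemble:
    """R configuration replicates plus their normalized metric tables."""
    if R < 1:
        raise ValueError("R must be >= 1")
    rng = np.random.default_rng(seed)
    reps, tables = [], []
    for _ in range(R):
        g = configuration_model(net, seed=int(rng.integers(2**31)))
        t = descriptors.normalize(descriptors.network_aggregates(g))
        reps.append(g)
        tables.append(t)
    return NullEnsemble(native=net, replicates=reps, tables=tables)


def _aggregate(table: descriptors.MetricTable, metric: str) -> float:
    if metric == "closeness":
        return float(table.nodes["norm_closeness"].mean())
    if metric == "betweenness":
        return float(table.nodes["norm_betweenness"].mean())
    if metric == "clustering":
        return float(table.nodes["clustering"].mean())
    raise ValueError(f"unknown aggregate metric {metric!r}")


def zscore(x: float, samples: Sequence[float]) -> ZScore:
    """z = (x - mu)/sigma with the sample (n-1) standard deviation over the
    ensemble values; flagged undefined when the ensemble has zero spread."""
    vals = np.asarray(samples, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least two ensemble values")
    mu = float(vals.mean())
    sd = float(vals.std(ddof=1))
    z = (x - mu) / sd if sd > 0 else None
    return ZScore(value=z, native=float(x), mean=mu, std=sd)


def ensemble_zscores(
    native: nx.Graph, R: int = 10, seed: int = 0,
    ensemble: Optional[NullEnsemble] = None,
) -> dict[str, ZScore]:
    """z-scores of the native normalized closeness, betweenness and
    clustering aggregates against R configuration replicates.

    The sample (n-1) standard deviation over the replicate aggregates is
    used; a zero-spread ensemble yields an undefined (flagged) z.
    """
    if R < 2:
        raise ValueError("z-scores need R >= 2 replicates")
    ens = ensemble if ensemble is not None else build_ensemble(native, R=R, seed=seed)
    native_t = descriptors.normalize(descriptors.network_aggregates(native))
    out = {}
    for metric in ("closeness", "betweenness", "clustering"):
        x = _aggregate(native_t, metric)
        out[metric] = zscore(x, [_aggregate(t, metric) for t in ens.tables])
    return out


def _exact_signed_rank_p(diffs: np.ndarray) -> float:
    """Two-sided exact p for the signed-rank statistic via the permutation
    distribution of W+ over all sign assignments (DP over doubled, tie-
    averaged ranks)."""
    absd = np.abs(diffs)
    ranks = stats.rankdata(absd)          # average ranks under ties
    r2 = np.rint(ranks * 2).astype(int)   # doubled -> integral
    total = int(r2.sum())
    # counts[w] = number of sign assignments with doubled W+ == w
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w_obs = int(np.rint(2 * ranks[diffs > 0].sum()))
    cdf = counts[: w_obs + 1].sum()
    sf = counts[w_obs:].sum()
    return float(min(1.0, 2.0 * min(cdf, sf)))


def paired_signed_rank(
    native_values: Sequence[float], null_values: Sequence[float],
) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired per-node samples.

    Zero differences are discarded (Wilcoxon's convention); if all
    differences vanish the test is degenerate and p = 1 is returned with a
    warning.  The exact permutation distribution is used for n <= 25
    retained pairs, the normal approximation with continuity correction
    beyond that.
    """
    x = np.asarray(native_values, dtype=float)
    y = np.asarray(null_values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; signed-rank p = 1",
                      stacklevel=2)
        return 1.0
    if d.size <= 25:
        return _exact_signed_rank_p(d)
    res = stats.wilcoxon(d, zero_method="wilcox", correction=True,
                         alternative="two-sided", method="approx")
    return float(res.pvalue)


def cross_species_test(distributions: Sequence[Sequence[float]]) -> np.ndarray:
    """Bonferroni-adjusted pairwise Kruskal-Wallis p-value matrix.

    Entry (i, j) is the Kruskal-Wallis p-value between groups i and j,
    multiplied by the number of unordered group pairs and capped at 1;
    the diagonal is NaN (same group).
    """
    groups = [np.asarray(g, dtype=float) for g in distributions]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    for i, g in enumerate(groups):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
    n_pairs = k * (k - 1) // 2
    mat = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            if np.ptp(np.concatenate([groups[i], groups[j]])) == 0:
                p = 1.0  # identical constant groups: no evidence either way
            else:
                p = float(stats.kruskal(groups[i], groups[j]).pvalue)
            mat[i, j] = mat[j, i] = min(1.0, p * n_pairs)
    return mat


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[Optional[float], Optional[float]]:
    """Pearson product-moment correlation with two-sided p (t transform).

    Returns ``(None, None)`` when either sample has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson needs equal-length samples of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None, None
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def hierarchical_dendrogram(
    feature_vectors: Sequence[Sequence[float]], method: str = "average",
) -> np.ndarray:
    """Agglomerative merge tree (SciPy linkage matrix) over feature vectors.

    Euclidean distance with average linkage (UPGMA) by default; input order
    fixes the leaf indices, so the tree is deterministic given the inputs.
    """
    X = np.atleast_2d(np.asarray(feature_vectors, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("need at least two feature vectors")
    return linkage(X, method=method, metric="euclidean")
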