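#!/usr/bin/env python
"""Descriptor suite over the emulated networks + published-column correlations.

Reads the edge lists written by 01, computes the per-network descriptor
table (density, diameter, barycenter, average degree/centralities/
clustering, Louvain modularity and communities), and the three Pearson
correlations across the published twelve-organism average-metric columns.
Writes results/analysis/descriptors.tsv and correlations.tsv.
"""

from pathlib import Path

import pandas as pd

from uprnet import (
    descriptors,
    detect_communities,
    network_io,
    pearson,
)
from uprnet.organisms import organism_table

NETS = Path("results/networks")
OUT = Path("results/analysis")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for path in sorted(NETS.glob("*.tsv")):
        with open(path) as fh:
            g = network_io.parse_interaction_tsv(fh, 0.400)
        t = descriptors.normalize(descriptors.network_aggregates(g))
        _, q, k = descriptors.detect_communities(g, seed=0)
        t.modularity, t.n_communities = q, k
        rows.append(descriptors.metric_report_row(path.stem.replace("_", " "), t))
    df = pd.DataFrame(rows).set_index("organism")
    df.to_csv(OUT / "descriptors.tsv", sep="\t", float_format="%.6g")
    print(df[["barycenter", "n_nodes", "edge_records", "density", "modularity",
              "n_communities"]].to_string())

    ref = organism_table()
    pairs = [
        ("avg_closeness", "avg_betweenness"),
        ("avg_degree", "avg_closeness"),
        ("avg_degree", "avg_betweenness"),
    ]
    crows = []
    print("\nPearson correlations across published average-metric columns:")
    for a, b in pairs:
        r, p = pearson(ref[a], ref[b])
        crows.append({"x": a, "y": b, "r": r, "p": p})
        print(f"  {a} vs {b}: r = {r:+.3f} (p = {p:.2g})")
    pd.DataFrame(crows).to_csv(OUT / "correlations.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
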