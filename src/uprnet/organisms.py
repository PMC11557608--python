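"""Published per-organism UPR network summary statistics.

These are the printed network-level features of the twelve native UPR
models (node counts, directed edge-record counts, density, diameter,
average degree/closeness/betweenness/clustering, modularity, community
count, and the barycenter protein).  They serve two roles: as reference
inputs for cross-column statistics (correlation, clustering of organisms)
and as size/hub profiles for the synthetic network emulator.

``edge_records`` follows the STRING TSV convention of one record per
direction, i.e. twice the undirected edge count.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["OrganismProfile", "ORGANISMS", "organism_table"]


@dataclass(frozen=True)
class OrganismProfile:
    name: str
    barycenter: str
    n_nodes: int
    edge_records: int  # 2M, directed-record convention
    density: float
    diameter: int
    avg_degree: float
    avg_closeness: float
    avg_betweenness: float
    avg_clustering: float
    modularity: float
    n_communities: int

    @property
    def n_edges(self) -> int:
        """Undirected edge count M."""
        return self.edge_records // 2

    @property
    def hub_label(self) -> str:
        """Primary barycenter protein label (first token when several are listed)."""
        return self.barycenter.split(";")[0].strip()


ORGANISMS: dict[str, OrganismProfile] = {
    p.name: p
    for p in [
        OrganismProfile("Homo sapiens", "HSPA5", 216, 5286, 0.114, 7, 25, 0.0020, 145.5, 0.522, 0.311, 5),
        OrganismProfile("Rattus norvegicus", "Hspa5", 210, 3862, 0.088, 6, 18, 0.0020, 161.2, 0.496, 0.374, 6),
        OrganismProfile("Mus musculus", "Hspa5", 231, 4900, 0.092, 6, 21, 0.0018, 170.7, 0.538, 0.354, 6),
        OrganismProfile("Macaca fascicularis", "HSPA5", 186, 2468, 0.072, 6, 13, 0.0020, 160.5, 0.437, 0.422, 7),
        OrganismProfile("Bos taurus", "HSPA5", 205, 3292, 0.079, 8, 16, 0.0019, 172.6, 0.447, 0.374, 6),
        OrganismProfile("Oryctologus cuniculis", "HSPA5", 174, 2598, 0.086, 6, 15, 0.0023, 134.7, 0.464, 0.367, 5),
        OrganismProfile("Gallus gallus", "HSPA5", 179, 2048, 0.064, 8, 11, 0.0020, 173.5, 0.395, 0.385, 7),
        OrganismProfile("Danio rerio", "hspa5", 214, 3240, 0.071, 8, 15, 0.0018, 181.3, 0.413, 0.375, 6),
        OrganismProfile("Drosophila melanogaster", "Hsc70-3", 57, 760, 0.238, 5, 14, 0.0089, 29.9, 0.560, 0.324, 3),
        OrganismProfile("Caenorhabditis elegans", "hsp-90", 109, 1212, 0.103, 7, 11, 0.0034, 98.9, 0.594, 0.450, 6),
        OrganismProfile("Saccharomyces cerevisiae", "KAR2", 150, 2834, 0.127, 6, 19, 0.0028, 108.0, 0.607, 0.352, 6),
        OrganismProfile("Arabidopsis thaliana", "BIP2; BIP3", 62, 1188, 0.314, 5, 19, 0.0092, 25.6, 0.680, 0.245, 3),
    ]
}


def lookup(name: str) -> OrganismProfile:
    """Case-insensitive organism lookup."""
    for key, prof in ORGANISMS.items():
        if key.lower() == name.strip().lower():
            return prof
    raise ValueError(
        f"unknown organism {name!r}; known: {', '.join(ORGANISMS)}"
    )


def organism_table() -> pd.DataFrame:
    """The reference summary statistics as a DataFrame indexed by organism."""
    df = pd.DataFrame([vars(p) for p in ORGANISMS.values()]).set_index("name")
    df.index.name = "organism"
    return df
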