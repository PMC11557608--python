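"""Ingestion of STRING-style TSV interaction records into simple graphs.

STRING exports one interaction record per direction, so a TSV carries 2M
rows for M undirected interactions; records are collapsed to undirected
edges here and the directed-record count is re-exposed for report parity
with the database convention.
"""

from __future__ import annotations

import csv
import io
import warnings
from typing import Iterable, Optional, Sequence, Union

import networkx as nx

__all__ = [
    "ParseError",
    "parse_interaction_tsv",
    "edge_record_count",
    "write_edgelist",
]


class ParseError(ValueError):
    """Raised for malformed interaction records; carries the 1-based line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def _looks_like_header(fields: Sequence[str], score_col: int) -> bool:
    try:
        float(fields[score_col])
    except (ValueError, IndexError):
        return True
    return False


def parse_interaction_tsv(
    text: Union[str, io.TextIOBase, Iterable[str]],
    score_threshold: float = 0.400,
    *,
    columns: Sequence[int] = (0, 1, 2),
    nodes: Optional[Iterable[str]] = None,
    strict: bool = False,
) -> nx.Graph:
    """Parse tab-separated interaction records into an undirected simple graph.

    Parameters
    ----------
    text
        TSV content as a string, open text file, or iterable of lines.
        A header row is auto-detected (non-numeric score field).
    score_threshold
        Minimum combined score for an interaction to be kept; the comparison
        is inclusive (``score >= threshold``), so the STRING medium-confidence
        cut of 0.400 keeps records printed exactly at 0.400.
    columns
        Indices of (protein_a, protein_b, combined_score) fields.
    nodes
        Optional explicit node list; declared nodes are retained even when
        isolated.  STRING TSVs themselves never carry isolated nodes.
    strict
        If True, an input with no parseable records raises ``ParseError``
        instead of returning an empty network.

    Notes
    -----
    Scores printed on STRING's integer 0-999 scale are auto-detected (any
    score > 1) and divided by 1000.  Self-pairs are dropped, (a,b)/(b,a)
    duplicates collapse to one undirected edge.
    """
    if not 0.0 <= score_threshold <= 1.0:
        raise ValueError(f"score_threshold must be in [0, 1], got {score_threshold}")
    a_col, b_col, s_col = columns

    if isinstance(text, str):
        lines = text.splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in text]

    records: list[tuple[str, str, float, int]] = []  # (a, b, score, line_no)
    first_data = True
    for line_no, raw in enumerate(csv.reader(lines, delimiter="\t"), start=1):
        if not raw or (len(raw) == 1 and not raw[0].strip()):
            continue
        if first_data and _looks_like_header(raw, s_col):
            first_data = False
            continue
        first_data = False
        needed = max(a_col, b_col, s_col) + 1
        if len(raw) < needed:
            raise ParseError(
                f"expected at least {needed} tab-separated fields, got {len(raw)}",
                line=line_no,
            )
        a, b = raw[a_col].strip(), raw[b_col].strip()
        if not a or not b:
            raise ParseError("empty protein identifier", line=line_no)
        try:
            score = float(raw[s_col])
        except ValueError:
            raise ParseError(f"non-numeric score {raw[s_col]!r}", line=line_no) from None
        if score < 0:
            raise ParseError(f"negative score {score}", line=line_no)
        records.append((a, b, score, line_no))

    if not records:
        if strict:
            raise ParseError("no interaction records found")
        g = nx.Graph()
        if nodes:
            g.add_nodes_from(nodes)
        return g

    # STRING convention: integer scores on a 0-999 scale.
    if any(s > 1.0 for _, _, s, _ in records):
        records = [(a, b, s / 1000.0, ln) for a, b, s, ln in records]
    for a, b, s, ln in records:
        if s > 1.0:
            raise ParseError(f"score {s} outside [0, 1]", line=ln)

    g = nx.Graph()
    if nodes:
        g.add_nodes_from(nodes)
    for a, b, s, _ in records:
        if a == b:
            continue
        if s >= score_threshold:
            g.add_edge(a, b)
    if g.number_of_edges() == 0:
        warnings.warn(
            "no interactions survive the score threshold; returning a "
            f"{g.number_of_nodes()}-node, 0-edge network",
            stacklevel=2,
        )
    return g


def edge_record_count(net: nx.Graph) -> int:
    """Directed-record count 2M matching the STRING TSV / report convention."""
    return 2 * net.number_of_edges()


def write_edgelist(net: nx.Graph, path_or_buf, score: float = 1.0) -> None:
    """Write the canonical edge-list TSV: sorted endpoint pairs, one undirected
    edge per line, with a constant combined score so the file round-trips
    through :func:`parse_interaction_tsv`."""
    close = False
    if isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__"):
        fh = open(path_or_buf, "w")
        close = True
    else:
        fh = path_or_buf
    try:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for a, b in sorted(tuple(sorted(map(str, e))) for e in net.edges()):
            fh.write(f"{a}\t{b}\t{score:.3f}\n")
    finally:
        if close:
            fh.close()
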