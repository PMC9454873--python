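"""Readers and writers for interaction networks, complex catalogs, protein
lists, and score tables.

All identifiers are treated as case-sensitive opaque strings; no aliasing or
identifier mapping is attempted, so parsed counts are reproducible byte for
byte. Edge lists are collapsed to simple undirected graphs: duplicate lines,
reversed duplicates, and self-interactions are dropped (with counts recorded
in a :class:`ParseReport`), because every downstream weight and centrality
assumes a simple graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

SCORE_COLUMNS = ["protein", "lid", "idc", "rank", "lidc", "predicted"]


@dataclass
class ParseReport:
    """Bookkeeping from :func:`read_interactions`."""

    lines_read: int = 0
    comments_skipped: int = 0
    edges_kept: int = 0
    duplicates_dropped: int = 0
    self_loops_dropped: int = 0


@dataclass
class ComplexCatalog:
    """Ordered list of protein complexes.

    Each complex is a ``(label, members)`` pair; members are unique within a
    complex but a protein may belong to several complexes.
    """

    complexes: list[tuple[str, frozenset[str]]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self):
        return iter(self.complexes)

    def proteins(self) -> set[str]:
        """Distinct proteins across all complexes."""
        out: set[str] = set()
        for _, members in self.complexes:
            out |= members
        return out

    def membership_index(self) -> dict[str, list[frozenset[str]]]:
        """Map each protein to the member sets of the complexes containing it."""
        idx: dict[str, list[frozenset[str]]] = {}
        for _, members in self.complexes:
            for p in members:
                idx.setdefault(p, []).append(members)
        return idx


@dataclass(frozen=True)
class GoldStandard:
    """Gold-standard essentiality labels.

    ``nonessential`` is optional; when both sets are given they must be
    disjoint.
    """

    essential: frozenset[str]
    nonessential: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.nonessential is not None and self.essential & self.nonessential:
            overlap = sorted(self.essential & self.nonessential)[:5]
            raise ValueError(
                f"essential and non-essential sets overlap (e.g. {overlap})"
            )


def read_interactions(path: str | Path, *, comment: str = "#") -> nx.Graph:
    """Read a two-column whitespace/tab edge list into a simple graph.

    Lines starting with ``comment`` are ignored.  Each remaining line must
    carry at least two tokens; the first two are the interacting pair and any
    extra columns (e.g. confidence scores) are ignored.  Duplicate and
    reversed-duplicate pairs collapse to one edge; self-interactions are
    dropped.  The resulting :class:`networkx.Graph` carries the
    :class:`ParseReport` under ``G.graph["parse_report"]``.

    Raises
    ------
    ValueError
        If the file contains no data lines, or a data line has only one token
        (the line number is named in the message).
    """
    path = Path(path)
    G = nx.Graph()
    report = ParseReport()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(comment):
                report.comments_skipped += 1
                continue
            report.lines_read += 1
            tokens = line.split()
            if len(tokens) < 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected two identifiers, got {tokens!r}"
                )
            u, v = tokens[0], tokens[1]
            if u == v:
                report.self_loops_dropped += 1
                continue
            if G.has_edge(u, v):
                report.duplicates_dropped += 1
                continue
            G.add_edge(u, v)
            report.edges_kept += 1
    if report.lines_read == 0:
        raise ValueError(f"{path}: empty edge list")
    if report.duplicates_dropped or report.self_loops_dropped:
        logger.info(
            "%s: dropped %d duplicate and %d self-loop lines",
            path, report.duplicates_dropped, report.self_loops_dropped,
        )
    G.graph["parse_report"] = report
    return G


def write_interactions(network: nx.Graph, path: str | Path) -> None:
    """Write an edge list, one ``u<TAB>v`` pair per line, sorted canonically.

    Isolated nodes are not representable in this format and are skipped with
    a warning.
    """
    path = Path(path)
    isolates = [n for n, d in network.degree() if d == 0]
    if isolates:
        logger.warning("%s: %d isolated nodes not written", path, len(isolates))
    edges = sorted(tuple(sorted(e)) for e in network.edges())
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for u, v in edges:
            fh.write(f"{u}\t{v}\n")


def read_complexes(path: str | Path, *, labeled: bool = False) -> ComplexCatalog:
    """Read a complex catalog, one complex per line.

    Members are whitespace-separated.  With ``labeled=True`` the first token
    of each line is a complex label; otherwise labels ``C0001`` ... are
    assigned in file order.  Empty lines are skipped with a logged warning.
    Duplicate members within a line are collapsed.
    """
    path = Path(path)
    complexes: list[tuple[str, frozenset[str]]] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            tokens = raw.split()
            if not tokens:
                logger.warning("%s: line %d empty, skipped", path, lineno)
                continue
            if labeled:
                label, members = tokens[0], tokens[1:]
            else:
                label, members = f"C{len(complexes) + 1:04d}", tokens
            if not members:
                logger.warning("%s: line %d has a label but no members, skipped",
                               path, lineno)
                continue
            complexes.append((label, frozenset(members)))
    catalog = ComplexCatalog(complexes)
    logger.info("%s: %d complexes, %d distinct proteins",
                path, len(catalog), len(catalog.proteins()))
    return catalog


def write_complexes(catalog: ComplexCatalog, path: str | Path,
                    *, labeled: bool = False) -> None:
    """Write a catalog, one complex per line, members sorted canonically."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for label, members in catalog:
            row = sorted(members)
            if labeled:
                row = [label] + row
            fh.write(" ".join(row) + "\n")


def read_protein_list(path: str | Path) -> set[str]:
    """Read a one-identifier-per-line list into a deduplicated set."""
    path = Path(path)
    out: set[str] = set()
    with path.open("r", encoding="utf-8") as fh:
        for raw in fh:
            token = raw.strip()
            if token:
                out.add(token)
    if not out:
        raise ValueError(f"{path}: empty protein list")
    logger.info("%s: %d identifiers", path, len(out))
    return out


def write_protein_list(proteins: Iterable[str], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for p in sorted(set(proteins)):
            fh.write(p + "\n")


def write_score_table(table: pd.DataFrame, path: str | Path,
                      predicted: set[str] | None = None) -> None:
    """Write a score table as TSV in final ranking order.

    Columns are ``protein  lid  idc  rank  lidc  predicted``; the
    ``predicted`` column is ``E``/``NE`` when a predicted-essential set is
    given (or already present in the table) and ``NA`` otherwise.  Output is
    deterministic byte for byte for a fixed table: the table's canonical
    ordering (descending LIDC, ties by ascending identifier) is enforced here.
    """
    if table.empty:
        raise ValueError("refusing to write an empty score table")
    out = table.copy()
    if predicted is not None:
        out["predicted"] = ["E" if p in predicted else "NE" for p in out["protein"]]
    elif "predicted" not in out.columns:
        out["predicted"] = "NA"
    out = out.sort_values(["lidc", "protein"], ascending=[False, True],
                          kind="mergesort")
    out[SCORE_COLUMNS].to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_score_table(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_score_table`."""
    table = pd.read_csv(path, sep="\t", dtype={"protein": str, "predicted": str})
    missing = [c for c in SCORE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing score-table columns {missing}")
    return table
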