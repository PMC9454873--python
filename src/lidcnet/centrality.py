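"""Phase 2: LID, IDC and combined LIDC scoring.

Local interaction density (LID) measures how densely a protein's neighbours
interact with one another: the number of edges among the neighbours divided
by the number of neighbours that participate in at least one such edge.
In-degree centrality of complex (IDC) counts, over every complex a protein
belongs to, its network interactions with co-members of that complex.  The
two are combined with a rank-dependent weight,

    LIDC(u) = LID(u) * (1 - RANK(u)/N) + IDC(u) * RANK(u)/N

where RANK(u) is u's 1-based position in the descending LID ordering and N
the number of proteins scored: proteins whose local density alone ranks them
highly keep their LID score, while lower-LID proteins are rescued (or not)
by their complex participation.

Every ordering here uses the same canonical deterministic tie-break:
descending score, then ascending protein identifier.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .io import ComplexCatalog

#: Columns of a score table, in output order (``predicted`` is added at
#: write time).
SCORE_TABLE_COLUMNS = ["protein", "lid", "idc", "rank", "lidc"]


def lid(network: nx.Graph, u, *, denominator: str = "interconnected") -> float:
    """Local interaction density of u.

    ``|E(u)| / |V(u)|`` where E(u) is the set of edges among u's neighbours
    and V(u), with the default ``denominator="interconnected"``, the set of
    neighbours having at least one edge to another neighbour.  With
    ``denominator="all"`` every neighbour counts (a sensitivity-analysis
    variant).  Returns 0 when the neighbours are pairwise non-adjacent.
    """
    if u not in network:
        raise ValueError(f"node {u!r} not in network")
    nbrs = list(network[u])
    sub = network.subgraph(nbrs)
    n_edges = sub.number_of_edges()
    if n_edges == 0:
        return 0.0
    if denominator == "interconnected":
        denom = sum(1 for n in nbrs if sub.degree(n) > 0)
    elif denominator == "all":
        denom = len(nbrs)
    else:
        raise ValueError(f"unknown denominator mode {denominator!r}")
    return n_edges / denom


def idc(network: nx.Graph, catalog: ComplexCatalog, u) -> int:
    """In-degree centrality of complex: edges from u to co-members, summed
    over every complex containing u.

    Co-members absent from the network contribute nothing; a co-member shared
    by two complexes is counted once per complex.  Proteins in no complex
    score 0.
    """
    if u not in network:
        raise ValueError(f"node {u!r} not in network")
    total = 0
    for _, members in catalog:
        if u in members:
            total += sum(1 for m in members
                         if m != u and network.has_edge(u, m))
    return total


def rank_by_lid(network: nx.Graph, *,
                denominator: str = "interconnected") -> dict:
    """1-based ranks from the descending LID ordering.

    Ties broken by ascending protein identifier, so ranks are a deterministic
    permutation of 1..N.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("cannot rank an empty network")
    scores = {v: lid(network, v, denominator=denominator) for v in network}
    ordering = sorted(scores, key=lambda v: (-scores[v], str(v)))
    return {v: r for r, v in enumerate(ordering, start=1)}


def lidc_scores(network: nx.Graph, catalog: ComplexCatalog, *,
                denominator: str = "interconnected") -> pd.DataFrame:
    """Score every protein of the network and return the full table.

    The returned DataFrame has columns ``protein, lid, idc, rank, lidc`` and
    is ordered by descending LIDC with the canonical tie-break; its row order
    is the final ranking.  N is the number of proteins in the network passed
    in (normally the pruned network), and IDC counts edges of that same
    network.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("cannot score an empty network")
    n = network.number_of_nodes()
    index = catalog.membership_index()
    lid_vals = {v: lid(network, v, denominator=denominator) for v in network}
    ranks = rank_by_lid(network, denominator=denominator)
    rows = []
    for v in network:
        member_sets = index.get(v, [])
        idc_v = sum(sum(1 for m in members if m != v and network.has_edge(v, m))
                    for members in member_sets)
        w = ranks[v] / n
        rows.append({
            "protein": str(v),
            "lid": lid_vals[v],
            "idc": idc_v,
            "rank": ranks[v],
            "lidc": lid_vals[v] * (1.0 - w) + idc_v * w,
        })
    table = pd.DataFrame(rows, columns=SCORE_TABLE_COLUMNS)
    table = table.sort_values(["lidc", "protein"], ascending=[False, True],
                              kind="mergesort").reset_index(drop=True)
    return table


def degree_centrality(network: nx.Graph) -> dict:
    """Plain degree per node — the classical centrality-lethality baseline."""
    return dict(network.degree())
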