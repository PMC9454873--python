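"""Independent brute-force reference implementations used as test oracles.

Everything here is written with plain loops and set arithmetic, deliberately
avoiding the code paths (and the vectorised helpers) of the package itself.
"""

from __future__ import annotations

import math


def node_weight(G, v) -> float:
    total = 0
    count = 0
    for u in G.neighbors(v):
        deg = 0
        for _ in G.neighbors(u):
            deg += 1
        total += deg
        count += 1
    return total / count if count else 0.0


def edge_weight(G, u, v) -> float:
    gu = {w for w in G.neighbors(u)}
    gv = {w for w in G.neighbors(v)}
    return len(gu & gv) / len(gu | gv)


def mean_std(values, ddof: int = 0):
    vals = list(values)
    n = len(vals)
    mean = sum(vals) / n
    var = sum((x - mean) ** 2 for x in vals) / (n - ddof)
    return mean, math.sqrt(var)


def cutoff(values, k: int, ddof: int = 0) -> float:
    mean, sigma = mean_std(values, ddof)
    return mean + k * sigma * (1.0 - 1.0 / (1.0 + sigma ** 2))


def prune_nodes(G, k: int):
    """Surviving node set of the node-reduction stage."""
    weights = {v: node_weight(G, v) for v in G.nodes()}
    theta = cutoff(weights.values(), k)
    return {v for v, w in weights.items() if w >= theta}, theta


def prune_edges(G, k: int):
    """Surviving edge set (and non-stranded nodes) of the edge stage."""
    weights = {frozenset((u, v)): edge_weight(G, u, v) for u, v in G.edges()}
    theta = cutoff(weights.values(), k)
    kept_edges = {e for e, w in weights.items() if w >= theta}
    kept_nodes = {v for e in kept_edges for v in e}
    return kept_edges, kept_nodes, theta


def lid(G, u) -> float:
    nbrs = list(G.neighbors(u))
    edges = []
    for i, a in enumerate(nbrs):
        for b in nbrs[i + 1:]:
            if G.has_edge(a, b):
                edges.append((a, b))
    if not edges:
        return 0.0
    connected = {x for e in edges for x in e}
    return len(edges) / len(connected)


def idc(G, catalog, u) -> int:
    total = 0
    for _, members in catalog:
        if u not in members:
            continue
        for m in members:
            if m != u and G.has_edge(u, m):
                total += 1
    return total


def rank_by_lid(G) -> dict:
    scores = [(v, lid(G, v)) for v in G.nodes()]
    ordering = sorted(scores, key=lambda t: (-t[1], str(t[0])))
    return {v: r for r, (v, _) in enumerate(ordering, start=1)}


def lidc(G, catalog) -> dict:
    n = G.number_of_nodes()
    ranks = rank_by_lid(G)
    out = {}
    for v in G.nodes():
        r = ranks[v]
        out[v] = lid(G, v) * (1 - r / n) + idc(G, catalog, v) * (r / n)
    return out


def jackknife(ordered_proteins, essential, max_rank: int):
    curve = []
    hits = 0
    for p in ordered_proteins[:max_rank]:
        if p in essential:
            hits += 1
        curve.append(hits)
    return curve
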