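"""Phase 1: rule-based pruning of unreliable nodes and edges.

A node's weight is the average degree of its neighbours — a proxy for how
well-connected its local environment is.  An edge's weight is the Jaccard-style
overlap of its endpoints' neighbourhoods — a proxy for interaction
reliability, since true interactions in dense modules share many partners.
Both distributions are thresholded with

    theta_k = alpha + k * sigma * (1 - 1/(1 + sigma^2)),   k in {1, 2, 3}

where alpha and sigma are the mean and standard deviation of the weight
values and k selects the low / medium / high cut-off.  Pruning runs in two
single-pass stages: nodes below the node-weight cut-off are removed first
(snapshot semantics — all weights are computed on the input network before
any removal), then edges below the edge-weight cut-off are removed from the
node-reduced network, and finally nodes stranded at degree 0 are dropped.
The strict ``<`` test means that when all weights are equal (sigma = 0)
nothing is removed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

#: Accepted spellings of the three cut-off levels.
LEVEL_NAMES = {"low": 1, "medium": 2, "high": 3}


def as_level(level: int | str) -> int:
    """Normalise a cut-off level to k in {1, 2, 3}.

    Accepts 1/2/3 or the names ``low`` / ``medium`` / ``high``.
    """
    if isinstance(level, str):
        try:
            return LEVEL_NAMES[level.lower()]
        except KeyError:
            raise ValueError(f"unknown cut-off level {level!r}; "
                             f"expected one of {sorted(LEVEL_NAMES)}") from None
    k = int(level)
    if k not in (1, 2, 3):
        raise ValueError(f"cut-off level must be 1, 2 or 3, got {k}")
    return k


@dataclass(frozen=True)
class WeightStatistics:
    """Mean, standard deviation, and count of a weight distribution."""

    mean: float
    stdev: float
    n: int


@dataclass(frozen=True)
class PruningReport:
    """Counts and thresholds from a two-stage pruning run."""

    level: int
    nodes_initial: int
    edges_initial: int
    nodes_after_node_reduction: int
    edges_after_node_reduction: int
    nodes_after_edge_reduction: int
    edges_after_edge_reduction: int
    node_threshold: float
    edge_threshold: float

    def as_dict(self) -> dict:
        return {
            "level": self.level,
            "nodes_initial": self.nodes_initial,
            "edges_initial": self.edges_initial,
            "nodes_after_node_reduction": self.nodes_after_node_reduction,
            "edges_after_node_reduction": self.edges_after_node_reduction,
            "nodes_after_edge_reduction": self.nodes_after_edge_reduction,
            "edges_after_edge_reduction": self.edges_after_edge_reduction,
            "node_threshold": self.node_threshold,
            "edge_threshold": self.edge_threshold,
        }


def node_weight(network: nx.Graph, v, *, degree_context: str = "network") -> float:
    """Average degree of v's neighbours.

    With ``degree_context="network"`` (default) neighbour degrees are taken in
    the full network passed in.  With ``"induced"`` they are taken in the
    subgraph induced by v and its neighbours, an alternative reading of the
    neighbourhood-subgraph definition exposed for sensitivity analysis.
    A degree-0 node has weight 0 by convention.
    """
    if v not in network:
        raise ValueError(f"node {v!r} not in network")
    nbrs = list(network[v])
    if not nbrs:
        return 0.0
    if degree_context == "network":
        return sum(network.degree(u) for u in nbrs) / len(nbrs)
    if degree_context == "induced":
        sub = network.subgraph([v, *nbrs])
        return sum(sub.degree(u) for u in nbrs) / len(nbrs)
    raise ValueError(f"unknown degree_context {degree_context!r}")


def node_weights(network: nx.Graph, *, degree_context: str = "network") -> dict:
    """All node weights at once (same semantics as :func:`node_weight`)."""
    return {v: node_weight(network, v, degree_context=degree_context)
            for v in network}


def edge_weight(network: nx.Graph, u, v) -> float:
    """Neighbourhood-overlap weight of an existing edge u-v.

    ``|Γ(u) ∩ Γ(v)| / |Γ(u) ∪ Γ(v)|`` with open neighbourhoods (u ∉ Γ(u)).
    For an existing edge the union always contains both u and v, so the value
    lies in [0, 1) and the denominator is never zero.
    """
    if not network.has_edge(u, v):
        raise ValueError(f"edge {u!r}-{v!r} not in network")
    gu, gv = set(network[u]), set(network[v])
    return len(gu & gv) / len(gu | gv)


def edge_weights(network: nx.Graph) -> dict:
    """Weight of every edge, keyed by the edge tuple as stored."""
    return {(u, v): edge_weight(network, u, v) for u, v in network.edges()}


def weight_statistics(values, *, ddof: int = 0) -> WeightStatistics:
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot take statistics of an empty weight list")
    return WeightStatistics(mean=float(arr.mean()),
                            stdev=float(arr.std(ddof=ddof)),
                            n=int(arr.size))


def cutoff_threshold(values, level: int | str, *, ddof: int = 0) -> float:
    """theta_k = alpha + k * sigma * (1 - 1/(1 + sigma^2)).

    ``alpha`` is the mean and ``sigma`` the standard deviation of ``values``
    (population by default; ``ddof=1`` selects the sample convention).  With
    all values equal, sigma = 0 and the threshold collapses to the mean for
    every k.
    """
    k = as_level(level)
    stats = weight_statistics(values, ddof=ddof)
    sigma = stats.stdev
    return stats.mean + k * sigma * (1.0 - 1.0 / (1.0 + sigma * sigma))


def prune_nodes(network: nx.Graph, level: int | str, *,
                degree_context: str = "network", ddof: int = 0) -> nx.Graph:
    """Remove every node whose weight falls strictly below theta_k.

    Snapshot semantics: all weights and the threshold are computed on the
    input network; removals do not trigger recomputation.  The returned graph
    records the threshold under ``G.graph["node_threshold"]``.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("cannot prune an empty network")
    weights = node_weights(network, degree_context=degree_context)
    theta = cutoff_threshold(weights.values(), level, ddof=ddof)
    keep = [v for v, w in weights.items() if w >= theta]
    pruned = network.subgraph(keep).copy()
    pruned.graph["node_threshold"] = theta
    logger.info("node reduction (k=%d): theta=%.6g, %d -> %d nodes, %d -> %d edges",
                as_level(level), theta,
                network.number_of_nodes(), pruned.number_of_nodes(),
                network.number_of_edges(), pruned.number_of_edges())
    return pruned


def prune_edges(network: nx.Graph, level: int | str, *, ddof: int = 0,
                drop_isolated: bool = True) -> nx.Graph:
    """Remove every edge whose weight falls strictly below theta_k.

    Weights and the threshold are computed on the network passed in (the
    node-reduced network in the two-stage pipeline).  Nodes stranded at
    degree 0 by edge removal are then dropped, so the survivors are exactly
    the endpoints of surviving edges.  An edgeless network is returned
    unchanged with a warning.
    """
    if network.number_of_edges() == 0:
        logger.warning("edge reduction skipped: network has no edges")
        pruned = network.copy()
        pruned.graph["edge_threshold"] = math.nan
        return pruned
    weights = edge_weights(network)
    theta = cutoff_threshold(weights.values(), level, ddof=ddof)
    pruned = network.copy()
    pruned.remove_edges_from([e for e, w in weights.items() if w < theta])
    if drop_isolated:
        pruned.remove_nodes_from(list(nx.isolates(pruned)))
    pruned.graph["edge_threshold"] = theta
    logger.info("edge reduction (k=%d): theta=%.6g, %d -> %d nodes, %d -> %d edges",
                as_level(level), theta,
                network.number_of_nodes(), pruned.number_of_nodes(),
                network.number_of_edges(), pruned.number_of_edges())
    return pruned


def prune_network(network: nx.Graph, level: int | str, *,
                  degree_context: str = "network",
                  ddof: int = 0) -> tuple[nx.Graph, PruningReport]:
    """Run the full two-stage pruning and report all stage counts.

    The same cut-off level k is applied to the node stage and, on the
    node-reduced network, to the edge stage.
    """
    k = as_level(level)
    n0, m0 = network.number_of_nodes(), network.number_of_edges()
    node_reduced = prune_nodes(network, k, degree_context=degree_context,
                               ddof=ddof)
    n1, m1 = node_reduced.number_of_nodes(), node_reduced.number_of_edges()
    if n1 == 0:
        report = PruningReport(
            level=k, nodes_initial=n0, edges_initial=m0,
            nodes_after_node_reduction=0, edges_after_node_reduction=0,
            nodes_after_edge_reduction=0, edges_after_edge_reduction=0,
            node_threshold=node_reduced.graph["node_threshold"],
            edge_threshold=math.nan)
        return node_reduced, report
    edge_reduced = prune_edges(node_reduced, k, ddof=ddof)
    report = PruningReport(
        level=k, nodes_initial=n0, edges_initial=m0,
        nodes_after_node_reduction=n1, edges_after_node_reduction=m1,
        nodes_after_edge_reduction=edge_reduced.number_of_nodes(),
        edges_after_edge_reduction=edge_reduced.number_of_edges(),
        node_threshold=node_reduced.graph["node_threshold"],
        edge_threshold=edge_reduced.graph["edge_threshold"])
    return edge_reduced, report
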