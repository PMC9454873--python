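"""Seeded generator of benchmark inputs with planted dense modules.

The generator emulates the structure the two-phase method assumes: a sparse
Erdos-Renyi background, a handful of internally dense planted modules
(standing in for protein complexes / dense sub-modules), a complex catalog
that overlaps the planted modules, and a gold-standard essential list
enriched in module members.  Everything is a deterministic function of a
single integer seed: the network, the catalog and the gold labels are drawn
from independent streams derived from that seed, so the full triple
round-trips byte for byte through the writers.

Identifiers follow the scheme ``P000001`` ... — sortable and collision-free,
which also exercises the canonical tie-break of the scoring phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np

from .io import (ComplexCatalog, GoldStandard, write_complexes,
                 write_interactions, write_protein_list)

# Stream tags keeping network / catalog / gold draws independent of each
# other and of call order.
_NETWORK_STREAM = 0
_CATALOG_STREAM = 1
_GOLD_STREAM = 2


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one benchmark triple.

    Defaults give a 640-protein network in which planted-module members are a
    small minority (~6%), mirroring the heavy-tailed structure of real
    interactomes where dense modules are rare; within-module density 0.9
    against background density 0.01 gives the clear dense-module signal the
    pruning phase is designed to isolate.
    """

    n_background: int = 600
    n_modules: int = 4
    module_size: int = 10
    p_in: float = 0.9
    p_background: float = 0.01
    p_attach: float = 0.01
    complex_coverage: float = 0.75
    label_noise: float = 0.0
    n_noise_complexes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_in", "p_background", "p_attach",
                     "complex_coverage", "label_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.p_in <= self.p_background:
            raise ValueError(
                "planted-structure spec requires p_in > p_background "
                f"(got {self.p_in} <= {self.p_background})")
        for name in ("n_background", "n_modules", "module_size"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth recorded at generation time."""

    modules: tuple[frozenset[str], ...]
    module_members: frozenset[str]
    all_nodes: frozenset[str]


def _ids(start: int, count: int) -> list[str]:
    return [f"P{i:06d}" for i in range(start, start + count)]


def _sample_pairs(rng: np.random.Generator, nodes: list[str],
                  p: float) -> list[tuple[str, str]]:
    """Each unordered pair of ``nodes`` independently with probability p."""
    n = len(nodes)
    if n < 2 or p == 0.0:
        return []
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(iu.size) < p
    return [(nodes[i], nodes[j]) for i, j in zip(iu[mask], ju[mask])]


def _sample_bipartite(rng: np.random.Generator, left: list[str],
                      right: list[str], p: float) -> list[tuple[str, str]]:
    if not left or not right or p == 0.0:
        return []
    mask = rng.random((len(left), len(right))) < p
    li, ri = np.nonzero(mask)
    return [(left[i], right[j]) for i, j in zip(li, ri)]


def generate_planted_network(spec: SyntheticSpec) -> tuple[nx.Graph, SyntheticTruth]:
    """Background graph with planted dense modules.

    Background nodes are connected pairwise with probability
    ``p_background``; each module's internal pairs with ``p_in``; each
    module-background pair with ``p_attach``.  Deterministic for a fixed
    seed.
    """
    rng = np.random.default_rng([_NETWORK_STREAM, spec.seed])
    background = _ids(1, spec.n_background)
    modules: list[list[str]] = []
    next_id = spec.n_background + 1
    for _ in range(spec.n_modules):
        modules.append(_ids(next_id, spec.module_size))
        next_id += spec.module_size

    G = nx.Graph()
    G.add_nodes_from(background)
    edges = _sample_pairs(rng, background, spec.p_background)
    for module in modules:
        G.add_nodes_from(module)
        edges += _sample_pairs(rng, module, spec.p_in)
        edges += _sample_bipartite(rng, module, background, spec.p_attach)
    G.add_edges_from(edges)

    truth = SyntheticTruth(
        modules=tuple(frozenset(m) for m in modules),
        module_members=frozenset().union(*map(frozenset, modules)) if modules
        else frozenset(),
        all_nodes=frozenset(G.nodes()))
    return G, truth


def generate_complex_catalog(truth: SyntheticTruth,
                             spec: SyntheticSpec) -> ComplexCatalog:
    """Catalog overlapping the planted modules.

    Each planted module is emitted as a complex with probability
    ``complex_coverage``; ``n_noise_complexes`` additional complexes of
    random background members (module-sized) model spurious catalog entries.
    """
    rng = np.random.default_rng([_CATALOG_STREAM, spec.seed])
    complexes: list[tuple[str, frozenset[str]]] = []
    for i, module in enumerate(truth.modules, start=1):
        if rng.random() < spec.complex_coverage:
            complexes.append((f"M{i:04d}", module))
    background = sorted(truth.all_nodes - truth.module_members)
    size = min(spec.module_size, len(background))
    for j in range(1, spec.n_noise_complexes + 1):
        if size >= 1:
            members = rng.choice(background, size=size, replace=False)
            complexes.append((f"X{j:04d}", frozenset(members.tolist())))
    return ComplexCatalog(complexes)


def generate_gold_standard(truth: SyntheticTruth,
                           spec: SyntheticSpec) -> GoldStandard:
    """Gold labels: module members essential, then symmetric label noise.

    Exactly ``floor(label_noise * n)`` proteins, drawn uniformly without
    replacement over all n nodes, have their label flipped; label_noise = 1
    inverts every label.  Deterministic per seed.
    """
    rng = np.random.default_rng([_GOLD_STREAM, spec.seed])
    nodes = sorted(truth.all_nodes)
    essential = set(truth.module_members)
    n_flip = int(spec.label_noise * len(nodes))
    if n_flip:
        flips = rng.choice(nodes, size=n_flip, replace=False)
        for p in flips:
            p = str(p)
            if p in essential:
                essential.discard(p)
            else:
                essential.add(p)
    nonessential = truth.all_nodes - essential
    return GoldStandard(essential=frozenset(essential),
                        nonessential=frozenset(nonessential))


def generate_benchmark(spec: SyntheticSpec
                       ) -> tuple[nx.Graph, ComplexCatalog, GoldStandard,
                                  SyntheticTruth]:
    """The full triple (network, catalog, gold) plus its ground truth."""
    network, truth = generate_planted_network(spec)
    catalog = generate_complex_catalog(truth, spec)
    gold = generate_gold_standard(truth, spec)
    return network, catalog, gold, truth


def write_benchmark(spec: SyntheticSpec, outdir: str | Path) -> dict:
    """Write edges.tsv, complexes.txt, essential.txt and truth.json.

    Returns the paths written, keyed by artifact name.
    """
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    network, catalog, gold, truth = generate_benchmark(spec)
    paths = {
        "edges": outdir / "edges.tsv",
        "complexes": outdir / "complexes.txt",
        "essential": outdir / "essential.txt",
        "truth": outdir / "truth.json",
    }
    write_interactions(network, paths["edges"])
    write_complexes(catalog, paths["complexes"])
    write_protein_list(gold.essential, paths["essential"])
    with paths["truth"].open("w", encoding="utf-8") as fh:
        json.dump({
            "spec": asdict(spec),
            "modules": [sorted(m) for m in truth.modules],
            "module_members": sorted(truth.module_members),
            "n_nodes": network.number_of_nodes(),
            "n_edges": network.number_of_edges(),
            "n_essential": len(gold.essential),
        }, fh, indent=2)
        fh.write("\n")
    return {k: str(v) for k, v in paths.items()}
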