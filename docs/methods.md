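# Methods

## Model and assumptions

`lidcnet` implements a two-phase pipeline for ranking candidate essential
proteins in an undirected, simple protein–protein interaction network
(PPIN). The underlying assumptions are (1) the centrality–lethality premise —
essential proteins concentrate in densely interconnected sub-modules — and
(2) that high-throughput interactomes carry enough spurious nodes and edges
that centralities computed on the raw network are diluted by noise. Phase 1
therefore removes topologically unreliable material before phase 2 scores
what remains. Because the method is purely topological, it inherits whatever
bias the input network has; it makes no use of expression, orthology or
sequence features.

### Phase 1: pruning

Node weight `W_v` is the mean degree of v's neighbours; edge weight `W_uv`
is the Jaccard-style overlap `|Γ(u) ∩ Γ(v)| / |Γ(u) ∪ Γ(v)|` with open
neighbourhoods (`u ∉ Γ(u)`), so an edge whose endpoints share no partners
scores 0 and an existing edge always scores strictly below 1 (both
endpoints sit in the union but never the intersection). Each weight
distribution is cut at

    θ_k = α + k·σ·(1 − 1/(1 + σ²)),   k ∈ {1, 2, 3},

a mean-plus-scaled-deviations rule whose damping factor `1 − 1/(1+σ²)`
shrinks the step when the distribution is nearly constant: as σ → 0,
θ_k → α for every k, and since removal is strict (`< θ_k`), a perfectly
regular graph is never pruned. Both stages use snapshot semantics — all
weights and the threshold are computed on the stage's input network and
removals do not trigger recomputation — so each stage is a single
deterministic pass. The node stage runs first; the edge stage then
recomputes weights on the node-reduced network; nodes stranded at degree 0
by edge removal are dropped, so the survivors are exactly the endpoints of
surviving edges.

### Phase 2: scoring

On the pruned network, local interaction density is
`LID(u) = |E(u)|/|V(u)|` with `E(u)` the edges among u's neighbours and
`V(u)` the neighbours having at least one edge to another neighbour
("interconnected" neighbours); `0/0` is defined as 0. LID is bounded by
`(deg(u) − 1)/2`, with equality on clique members. In-degree centrality of
complex, `IDC(u)`, sums u's network edges to co-members over every complex
containing u; a co-member shared by two complexes counts once per complex,
co-members absent from the network contribute nothing, and no normalisation
by complex size is applied. The combined score

    LIDC(u) = LID(u)·(1 − RANK(u)/N) + IDC(u)·RANK(u)/N

is a convex combination (RANK/N ∈ (0, 1]): proteins whose local density
already ranks them near the top keep (most of) their LID, while low-LID
proteins are dominated by their complex participation. Every ordering uses
one canonical tie-break — descending score, then ascending identifier — so
all outputs are byte-deterministic.

### Evaluation

Predicted sets come from the final LIDC ordering either as top-k (the
100–600 ranking ranges; the range end is a free parameter) or as the top
fraction (conventionally 20%). Precision, recall and F-score are computed
over an explicit universe, by default the scored (pruned) network, with
anything not listed essential treated as non-essential. The jackknife curve
is the cumulative count of gold-essential proteins along the ranking.

## Parameters and switches

| switch | default | meaning |
|---|---|---|
| `level` | — | k ∈ {1,2,3} ≡ low/medium/high; same k for both stages |
| `degree_context` | `network` | neighbour degrees in the full current network; `induced` restricts to the subgraph on v and its neighbours |
| `ddof` | 0 | σ is the population standard deviation; 1 selects the sample convention |
| `lid_denominator` | `interconnected` | `all` divides by every neighbour instead (sensitivity variant) |
| `fraction` / `rounding` | 0.2 / `ceil` | top-fraction count = ⌈0.2·N⌉; `round`/`floor` exposed because published top-20% counts do not follow one rounding convention consistently |
| `recall_denominator` | `universe` | recall against gold essentials present in the evaluated network; `full` uses the whole gold list |
| `strict_gold` | off | when on, proteins absent from both gold lists are excluded from the confusion bookkeeping |

The defaults are the package's primary configuration; the switches exist
because each of these conventions is genuinely underdetermined by common
usage in the field, and calibrating against published pruning counts on a
specific real interactome is the intended way to fix them for that dataset.
When reproducing published counts, a small grid over
`degree_context × ddof × rounding` is the first thing to try; the CLI
exposes all three.

## Synthetic benchmark

`SyntheticSpec` defaults: 600 background proteins, 4 planted modules of 10,
within-module edge probability `p_in = 0.9`, background probability
`p_background = 0.01`, module-to-background attachment `p_attach = 0.01`,
complex coverage 0.75 with 2 noise complexes, label noise 0, identifiers
`P000001…`. The generator emulates the three real inputs: a sparse
interactome with dense modules, a complex catalog overlapping those
modules, and a gold list enriched in module members (module members are
essential; `⌊label_noise·n⌋` labels are then flipped uniformly).

Module members are kept a small minority (~6% of nodes) deliberately: the
k=3 cut-off sits three damped standard deviations above the mean weight, so
a planted-module weight mode can only survive it when it forms a genuine
upper tail rather than a balanced second mode — the same heavy-tailed shape
real interactomes have. With these defaults the expected background node
weight is ≈ 6.5 against ≈ 11 inside modules, which keeps all three cut-off
levels non-degenerate.

What the generator does **not** emulate: scale-free/duplication-divergence
degree structure, overlapping modules, experimentally correlated false
positives, or biased (hub-enriched) gold standards. Passing tests on this
benchmark therefore demonstrate that the implementation recovers planted
dense structure under the method's own assumptions — not that the method's
published performance on a real interactome is reproduced.

## Numerical and design choices

- All randomness flows from one integer seed through independent
  `numpy` `SeedSequence` streams (network / catalog / gold), so the full
  triple is reproducible byte for byte and regenerating the gold list at a
  different noise level does not perturb the network.
- Neighbour degrees default to the full current network rather than the
  induced neighbourhood subgraph: the single-pass pruning procedure is
  stated over neighbour degrees unqualified, and the full-network reading
  keeps the node weight monotone in neighbour connectivity. The induced
  alternative is one switch away.
- Thresholding is strict `<`, so σ = 0 (all weights equal) removes nothing
  rather than everything.
- Degenerate inputs: a degree-0 node has node weight 0; an edgeless network
  skips the edge stage with a warning (threshold recorded as NaN); a network
  emptied by the node stage yields a report with zero "after" counts; LID of
  a node with pairwise non-adjacent neighbours is 0; metrics with an empty
  denominator are 0 by convention.
- Edge-list files cannot represent isolated nodes; the writers warn and the
  pipeline never needs them (they cannot survive phase 1).

## Problem sizes

The default test and acceptance runs use 640-protein synthetic networks
(~2200 interactions), 200 random graphs of ≤ 50 nodes for oracle
equivalence, and 10 seeds × 3 noise levels for the robustness sweep — sizes
at which every brute-force oracle is exact and the whole suite runs in
seconds while leaving all three cut-off levels non-trivial.

## Known limitations

- Real-interactome pruning counts depend on the convention switches above;
  no single default set is guaranteed to match a given published table
  without the calibration grid.
- Recall on the pruned universe is not comparable to recall on the full
  network; the `recall_denominator` switch makes the choice explicit rather
  than hiding it.
- IDC is an unnormalised count, so large complexes dominate; this mirrors
  the method definition but means catalogs with very uneven complex sizes
  skew LIDC toward large-complex members.
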