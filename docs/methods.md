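# Methods

This note documents the model, the algorithmic and numerical choices, and
the synthetic fixtures behind `loopnest`, in the spirit of a methods
supplement.  It states no empirical result that the test suite does not
itself compute.

## The decomposition model

A weighted planar network is viewed as a hierarchy of nested loops: thin
vessels subdivide the regions bounded by thicker ones.  The hierarchical
loop decomposition makes that hierarchy explicit by deleting edge chains in
order of increasing strength and recording each resulting loop fusion as an
internal node of a full binary tree (the *nesting tree*).  The tree node
carries the fused loop's area (sum of the merged areas), its degree (number
of elementary-loop descendants) and the strength `h` of the deleted chain;
under the minimum strength rule the `h` sequence is non-decreasing along the
merge order, so `h` acts as a resolution axis: cutting the tree at height
`h*` reproduces the network simplified to vessels stronger than `h*`.

Assumptions on the input: a connected, straight-line embedded graph with
strictly positive link weights, no multi-links and no self-loops, and a
non-crossing embedding (validated with an STRtree sweep; the check can be
switched off for noisy digitizations where hairline crossings are artifacts
of skeletonization).  Faces are computed geometrically from the embedding by
half-edge traversal in counter-clockwise angular order; the face of largest
absolute signed area is the outer face.  Coordinates are therefore
mandatory; purely combinatorial embeddings are out of scope.

Degenerate and awkward cases are handled explicitly:

- **Ties.**  The algorithm needs a strict weight order.  At load time only
  tied weights receive a seeded uniform perturbation of magnitude at most
  1e-9 × (smallest weight); untied weights are preserved exactly, so the
  generated models (which use distinct ranks 1..L) are processed bit-exactly.
- **Tree-like components** are pruned to a fixpoint before decomposition; a
  graph with no cycle at all is rejected.
- **Bridges** (chains bordering the same face twice) would disconnect the
  graph when removed.  Each bridge's weight is raised to
  `min(max side₁, max side₂) × (1 + 1e-9)` up front, so the weaker side
  finishes merging before its bridge is touched; during the decomposition a
  popped chain whose two sides resolve to the same current loop is simply
  deleted, never merged.  These deletions also cover chains made redundant
  by earlier merges.
- **Chain fusion.**  When a deletion leaves a junction of degree 2, the two
  incident chains fuse and the strength is re-aggregated under the
  configured rule, so the next removal is always the global minimum among
  current chains.  A lazy priority queue (heap entries invalidated on
  fusion) implements this in O(L log L).
- **A single cycle** with all vertices of degree 2 is one closed chain
  bounding one face; its removal merges that face with the exterior.

### Exterior conventions

`single_exterior` treats the unbounded region as one zero-area loop.
Composites that contain the exterior keep the area of their internal
content, and the cumulative size distribution is taken over every node with
positive area; only the zero-area exterior/phantom leaves are excluded.
This matters: in additive architectures almost every composite contains the
exterior, and excluding them would collapse the CSD to a step function
rather than the straight line that characterizes additive nestedness.

`phantom_boundary` scales the perimeter by 1.2 about its centroid, placing
one phantom vertex per perimeter junction (all perimeter vertices when
fewer than three junctions exist), joined into an enclosing polygon, with
one connector per junction; all added links carry infinite weight.  This
fragments the outside into one phantom loop per connector and preserves
which part of the boundary a loop broke through.  In practice the phantom
loops become connected through finite interior chains before any sentinel
link is popped, so phantom trees close with finite merge strengths; chains
bordering the true outer face are discarded without a merge, keeping the
outer face out of the tree.  The 1.2 scale and one-connector-per-junction
layout are conventions, adequate for convex perimeters; strongly non-convex
perimeters may need a larger scale to avoid crossings.

## Metrics

**Partition asymmetry.**  Two normalizations are provided.  The default,
`q = |r − s| / (r + s − 2)` with `q(1,1) = 0`, is the van Pelt branch-power
form; it gives the additive (caterpillar) architecture of degree `d` the
exact subtree asymmetry `(d − 2)/(d − 1)` and the perfectly balanced
architecture exactly 0.  The variant `q = |r − s| / (r + s)` ("degree_sum")
discounts partitions of small total degree.  The difference matters for
self-similar networks: the nested lattice model's iterated building unit is
four elements joining sequentially, whose partitions `(1,1), (2,1), (3,1)`
have van Pelt q of `0, 1, 1` — a fine-scale floor of 2/3 that dominates any
uniform average and masks larger-scale differences between architectures.
Under the degree-sum form the same unit contributes `0, 1/3, 1/2`, and the
graded effect of architectural disorder (nested → nested5 → nested10 →
random lines) becomes monotone and statistically resolvable; the ensemble
ordering test therefore uses it.  Subtree asymmetry defaults to uniform
weights over all internal nodes of the subtree; a `weight_fn` hook supports
no-averaging or shallow-window variants.  The averaged asymmetry `Λ(d)` is
the mean of `A(n)` over nodes within ±0.5 of `log₂ d` (window configurable;
an exact-degree variant is provided); empty windows yield NaN, not errors.
Exterior-containing nodes count in degrees and in Λ (topology metrics) but
never contribute area.

**Cumulative size distribution.**  `P(A > a)` over the multiset of node
areas normalized by the total, evaluated at all distinct areas as a
right-continuous step function.  The adjusted form `ã P(A > a)` is flat when
`P ∝ 1/a`, the signature of scale-invariant (multiplicative) architecture;
slopes are fitted by OLS on linear or log-log axes over a configurable
abscissa range (the flatness checks use the central two decades of the area
range, away from the terminal-loop floor and the finite-size roll-off).

**Strahler statistics.**  Orders follow the standard recursion (leaves 1;
equal children increment).  Stream counts `N_ω` count maximal same-order
paths via stream heads.  The bifurcation ratio fit regresses `ln N_ω` on
`ω` constrained through `(1, ln N₁)`, discards the highest order (a single
noisy count), and reports the slope's standard error from the residuals;
with fewer than three orders the two-point ratio `N₁/N₂` is returned,
flagged, since no fit is possible.  `R_B` is base-free.

## Segmentation and cleaning

Sectors are the *k largest-degree disjoint subtrees*: the largest threshold
m is located such that at least k disjoint subtrees reach degree m (a node
qualifies where its degree reaches m but neither child's does), and the k
largest qualifying subtrees become the sectors.  This follows the notion of
"high-level nodes that correspond to major loops" rather than literally
cutting the k−1 strongest merges — the final merges of any decomposition
are single-face accretions (small loops hugging the strongest vessels), so
strength-based cutting only peels singletons.  Faces accreted above the
sector roots stay unassigned.  The strength-cutoff variant returns the
maximal subtrees whose root merge strength is below `h*`.  Segments are
connected regions of the source graph by construction (a nesting-tree
subtree is a contiguous merged loop).

Cleaning targets digitization bias: spuriously strong small loops along
major veins survive deep into the decomposition and then join large
composites one at a time, producing partitions with `q` near 1.  Internal
nodes with `q > 0.97` (threshold configurable; the q-histogram helper
suggests one at the last prominent interior minimum) lose their
smaller-degree child subtree and are spliced out, with degrees and areas
recomputed.  Cleaning defaults to the degree-sum normalization, under which
the 0.97 cutoff selects only small loops joining composites two orders of
magnitude larger; under the van Pelt form every single-loop accretion has
`q = 1` exactly, so the same cutoff acts as an aggressive prune of all
additive fine structure — available, but not a selective cleaner.

## Synthetic fixtures

All generated networks share one substrate — the hexagonal patch of the
triangular lattice with `n` rings (`1 + 3n(n+1)` vertices, `9n² + 3n`
links, `6n²` faces; `n = 16` gives the 817-vertex study size) — and one
weight multiset, the ranks `1..L`, so architectures differ only in the
placement of weights:

- `gradient`: descending weight with distance of the link midpoint from the
  left-most vertex (thick near the source).  Decomposes additively.
- `random_links`: seeded uniform permutation; no long-range order.
- `nested`: the three families of lattice lines are ranked by recursive
  bisection (boundary and central lines order 0; bisectors of order-k spans
  order k+1, lower index winning even-span ties), and descending weights
  are dealt line by line in ascending (order, family, index).  Keeping only
  lines of order ≤ k leaves a triangular lattice of doubled spacing, so the
  model is genuinely self-similar.
- `nested5` / `nested10`: nested with k = 5 (10) seeded transpositions of
  line pairs.  The pairs are drawn from a single seeded permutation prefix,
  so for a fixed seed the pairs swapped by nested5 are a subset of those
  swapped by nested10 — common random numbers that make paired comparisons
  across disorder levels efficient.
- `random_lines`: a full seeded permutation of the line order (coherent
  lines, random ranking).
- `peaks`: descending weight with distance to the nearest of seven
  equidistant points (the center plus six half-radius hexagon corners;
  positions configurable).  Thickness is maximal at the peaks, so the
  decomposition accretes each basin face-by-face onto growing far-field
  composites — the asymmetry changes monotonicity at the basin scale, but
  the basins are not subtrees and cannot be recovered by tree cutting.
- `assign_sector_weights`: the complementary, vein-like geometry — thick
  along the inter-point ridges and the perimeter, thin deep inside each
  sector — for which the sectors are high-level subtrees; this is the
  ground-truthed fixture for the segmentation tests (k = 7 recovers the
  nearest-point partition of the assigned faces).
- `plant_contamination`: emulates non-uniform staining by boosting, for a
  seeded sample of faces touching the central (strongest) lattice lines,
  the off-line boundary links into 0.90–0.98 of the top weight.  The
  cleaning-recovery test uses 150 such faces on the 16-ring nested lattice,
  which distorts Λ(d) at plateau degrees by well over the 0.05 acceptance
  margin before cleaning.

What the fixtures do **not** emulate: polydisperse loop areas (all terminal
loops are unit lattice triangles, so area- and degree-based statistics
coincide more tightly than in real venation), curved vessels, measurement
noise in coordinates, and open (unclosed) veinlets beyond what pruning
removes.  Passing tests on these fixtures therefore validate the
algorithmic machinery and the metric signatures of additive, self-similar
and disordered architectures — not the full variability of digitized
specimens.

## Test and acceptance conditions

Problem sizes were chosen once: oracle-equivalence checks run on all
hand-built graphs with ≤ 8 faces and seeded 1-ring lattices, where an
independent brute-force implementation (faces, chains and strengths
recomputed from scratch after every deletion, loops identified by
point-in-polygon against the original face reference points) must reproduce
the merge-event sequence exactly; the CSD-slope and cleaning checks run on
the full 16-ring lattice; the disorder-ordering ensemble uses 20 seeds on
the 8-ring lattice with per-seed mean Λ (degree-sum) over the mid band
log₂ d ∈ [3, 7], one-sided Mann–Whitney tests for nested < nested5 and
nested10 < random lines, a paired Wilcoxon test for nested5 < nested10
(coupled by the shared swap prefix), and a one-sided test of
random links > random lines on log₂ d ∈ [3, 4], where the random-links
signature — low-order loops joining high-order composites directly — is
concentrated.
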