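# loopnest

Hierarchical loop decomposition of weighted planar networks.

Many biological distribution networks — the venation of dicotyledonous
leaves, the arterial vasculature of the rodent neocortex, insect wings —
are planar graphs dense with nested closed loops.  Classical tree metrics
(Horton–Strahler stream orders, van Pelt branch asymmetry) cannot be applied
to them directly because loops break the tree structure.  `loopnest` maps a
weighted planar "loopy" graph to a **binary nesting tree** that encodes its
hierarchical architecture, and then quantifies that architecture with tree
metrics.  It is aimed at people comparing digitized vasculature with the
output of generative or optimization models.

## The decomposition

The input is an embedded graph whose *links* carry positive widths.  After
pruning tree-like appendages, links are grouped into *edge chains* (maximal
paths through degree-2 junctions) with strength `S = min` of the member
widths (median/max are options).  The algorithm then repeats:

1. order the current chains by strength (ties are broken by a seeded,
   infinitesimal perturbation at load time);
2. delete the globally weakest chain;
3. if it separated two distinct loops, merge them — a node of the nesting
   tree at height `h` = deleted strength, with area `A = A₁ + A₂` and degree
   `d = d₁ + d₂`; re-collapse any junction that dropped to degree 2,
   re-aggregating chain strengths.

Leaves of the tree are the elementary faces of the embedding plus the
exterior — either one zero-area exterior loop, or (in `phantom_boundary`
mode) a ring of phantom loops tied to the perimeter by sentinel-weight
connectors, which preserves boundary neighborhood information.  Bridges are
handled up front by lifting their weight just above the weaker side they
would disconnect.

On the nesting tree the package computes:

- **partition asymmetry** `q = |r − s| / (r + s − 2)` of each bifurcation
  with subtree degrees `r`, `s` (a degree-sum variant `|r − s|/(r + s)` is
  available and is the default for data cleaning); **subtree asymmetry**
  `A(n)` = weighted mean of `q` over the subtree; **averaged asymmetry**
  `Λ(d)` over a log₂-degree window.  A purely additive history of degree
  `d` ("short" caterpillar trees) has `A = (d−2)/(d−1)`; a purely
  multiplicative one ("tall" balanced trees) has `A = 0`;
- **cumulative size distribution** `P(A > a)` over all node areas (total
  area normalized to 1) and the **adjusted CSD** `a·P(A > a)`, flat for
  scale-invariant architectures;
- **Strahler orders**, stream counts `N_ω` and the **bifurcation ratio**
  `R_B` from a least-squares fit of `log N_ω` vs `ω` through `(1, log N₁)`
  with the noisy highest order discarded;
- **segmentation** of the graph into major sectors (the k largest-degree
  disjoint subtrees, or a strength cutoff) and **cleaning** of spuriously
  strong minor loops (`q > 0.97`), as needed for digitized specimens with
  staining bias.

A generators module builds all study fixtures: hexagonal patches of the
triangular lattice (16 rings → 817 vertices) and the architecture models
`gradient`, `random_links`, `nested`, `nested5`, `nested10`, `random_lines`
and `peaks`, which share one weight multiset and differ only in where the
weights go.

## Worked example

```python
from loopnest import (ModelSpec, assign_model_weights, bifurcation_ratio,
                      cumulative_size_distribution, decompose, fit_slope,
                      stream_counts, subtree_asymmetry, triangular_lattice_hex)

lattice = triangular_lattice_hex(16)                       # 817 vertices
graph = assign_model_weights(lattice, ModelSpec("gradient"))
tree = decompose(graph, mode="single_exterior", strength_rule="min", seed=0)
print(f"faces: {sum(1 for n in tree.leaves() if not n.exterior)}, "
      f"merges: {len(tree.internal_nodes())}")
csd = cumulative_size_distribution(tree)
fit = fit_slope(csd, a_range=(0.1, 0.9), axes="linear")
print(f"CSD slope on [0.1, 0.9]: {fit.slope:.4f} +- {fit.stderr:.4f}")
print(f"root asymmetry A: {subtree_asymmetry(tree, tree.root):.4f}")
rb = bifurcation_ratio(tree)
print(f"bifurcation ratio R_B: {rb.ratio:.1f} (two-point fallback: {rb.two_point})")
```

prints

```
faces: 1536, merges: 1536
CSD slope on [0.1, 0.9]: -0.5000 +- 0.0000
root asymmetry A: 0.9993
bifurcation ratio R_B: 1537.0 (two-point fallback: True)
```

The gradient model is the archetype of *additive* nestedness: loops join a
single running composite one at a time, so the tree is a caterpillar — the
CSD is a straight line of slope −1/2, the asymmetry is near 1, and only two
Strahler orders exist (hence the flagged two-point ratio).  The *nested*
model on the same lattice is the multiplicative archetype: `A(root) ≈ 0.58`,
stream counts `[1537, 384, 96, 24, 6, 3, 1]` with `R_B ≈ 3.8`, and an
adjusted CSD that is flat on log-log axes (fitted slope `0.009`).

The same pipeline is available from a shell:

```sh
loopnest generate --model nested --rings 16 --seed 7 --out net.tsv
loopnest decompose net.tsv --mode single --strength min --seed 7 --out tree.json
loopnest metrics tree.json --out-dir metrics/
loopnest segment tree.json --k 6 --out sectors.tsv
loopnest clean tree.json --q-threshold 0.97 --out cleaned.json
```

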