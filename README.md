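# phylocircuit

Circuit-theoretic analysis of unrooted phylogenetic networks.

Phylogenetic networks generalize trees by allowing cycles, which model
reticulate events such as hybridization and recombination. When the genetic
distance carried by an edge is read as an *electrical resistance*, the
distance between two taxa becomes the effective resistance between the
corresponding leaves — branching lineages combine like parallel resistors
(Ohm's law, `R = R1·R2/(R1+R2)`) instead of being discarded the way a
minimum-path distance discards them.

This package implements that theory for **1-nested (level-1)** networks —
simple connected graphs whose labelled leaves have degree 1, whose internal
nodes have degree ≥ 3, and whose edges each lie in at most one cycle — and
begins the study of **2-nested** networks (edges in at most two cycles,
obtained by inserting chords).

The core results it makes computable:

* the resistance metric `d_N^R` of a positive-weighted 1-nested network is
  **Kalmanson** (circular decomposable): for some circular order of the taxa,
  `max{d_ij + d_kl, d_jk + d_il} ≤ d_ik + d_jl` for every quadruple in
  cyclic order;
* the unique weighted circular split system with `d_s = d_N^R` can be built
  **directly from the network**: every displayed split gets the sum of its
  display weights — `w(e)` for a bridge display, `a·x/z` for a pair of
  cycle edges with weights `a`, `x` in a cycle of total weight `z` — and
  this system displays *exactly* the splits of `N`, so the unweighted
  network class is recovered by taking the smoothed exterior (`L`) of the
  split network;
* the vectors `x(N)` with `x_ij = 2^(k−b_ij)` (k non-trivial bridges,
  `b_ij` of them separating `i` from `j`) are the vertices of the balanced
  minimum evolution polytopes BME(n, k); minimizing `x·d_N^R` over them by
  exhaustive enumeration selects exactly the refinements of the generating
  class;
* binary triangle-free 1-nested networks are counted by
  `C(n−3, k)·(n+k−1)!/(2k+2)!!` and enumerated explicitly; their 2-nested
  chordings number 6, 120 and 2790 for n = 4, 5, 6.

It also provides the minimum-path analogue `S_w`, the weighted exterior map
`L_w`, Y-Δ (star-triangle) resistance transforms, marguerite counts for
cycle split-networks, Jukes–Cantor/Kimura distance calibration for the
resistance analogy, and seeded generators used by the test suite.

## Worked example

A 6-cycle with one heavy edge (weight 95, all other edges weight 1, unit
pendant leaf edges):

```python
from fractions import Fraction as F
import phylocircuit as pc

net = pc.PhyloNetwork.from_edges([
    ("c0", "c1", F(95)), ("c1", "c2", F(1)), ("c2", "c3", F(1)),
    ("c3", "c4", F(1)), ("c4", "c5", F(1)), ("c5", "c0", F(1)),
    (1, "c0", F(1)), (2, "c1", F(1)), (3, "c2", F(1)),
    (4, "c3", F(1)), (5, "c4", F(1)), (6, "c5", F(1)),
])

d = pc.resistance_leaf_vector(net)          # exact rational resistances
s = pc.rw_direct(net)                       # weighted circular split system
order = pc.find_kalmanson_order(d)          # exhaustive circular-order search
rebuilt = pc.L_exterior(
    pc.circular_decompose(d, order).base_with_trivial(), order=order)
```

printing

```
d(1,2) = 27/4  d(2,3) = 299/100
weight of {2,3}|{1,4,5,6}: 19/20
split metric equals resistance: True
Kalmanson order: (1, 2, 3, 4, 5, 6)
recovered the unweighted network: True
```

`d(1,2) = 1 + 95·5/100 + 1 = 27/4`: the heavy edge and the complementary
five-edge arc act as parallel resistors. The split `{2,3}|{1,4,5,6}` is cut
by the heavy edge together with one unit edge, so its weight is
`95·1/(95+1+1+1+1+1) = 19/20 = 0.95`. The split metric of the constructed
system reproduces the resistance vector exactly, and decomposing the metric
and taking the exterior recovers the network.

The same pipeline is available from the shell:

```sh
phylocircuit fixtures gen --kind 1nested --n 6 --seed 42 -o net.json
phylocircuit resistance net.json
phylocircuit rw net.json -o splits.nex     # opens in SplitsTree
phylocircuit count --nested 2 --n 5        # -> 120
```

## Layout

| module | contents |
| --- | --- |
| `phylocircuit.network` | `PhyloNetwork`, splits, circular orders, bridges, blocks, nestedness, Σ, consistent orders |
| `phylocircuit.distance` | resistance (exact/float), min-path, series-parallel oracle, Y-Δ, Kalmanson tests |
| `phylocircuit.splits` | weighted circular split systems, split metric, circular decomposition |
| `phylocircuit.transforms` | `rw_direct`/`rw_metric` (R_w), `sw` (S_w), `L_exterior`/`lw` (L, L_w), marguerites |
| `phylocircuit.bme` | BME(n, k) vectors, counting, enumeration, functional minimization |
| `phylocircuit.twonested` | chord insertion, 2-nested enumeration and counts |
| `phylocircuit.seqdist` | Jukes–Cantor, Kimura 2-parameter, parallel recombination calibration |
| `phylocircuit.generate` | seeded random 1-/2-nested networks, K₃,₃ counterexample |
| `phylocircuit.io` / `phylocircuit.cli` | JSON/GraphML networks, PHYLIP/NEXUS distances, NEXUS SPLITS, `phylocircuit` CLI |

See `docs/methods.md` for the models, conventions and design decisions.
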