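# Methods

This note records the models implemented in `phylocircuit`, the conventions
chosen where a definition is open to interpretation, and what the test suite
does and does not establish.

## Networks and the resistance model

A phylogenetic network on `[n]` is a simple connected graph with `n`
degree-1 leaves labelled bijectively by `1..n` and all internal nodes of
degree ≥ 3; networks are unrooted and undirected. Edge weights are
non-negative reals interpreted as resistances. Structural classes are read
off the biconnected blocks: a network is 1-nested when every block with
more than one edge is a simple cycle, and 2-nested when every such block is
a cycle or a theta (two degree-3 hub nodes joined by three internally
disjoint paths, i.e. a chorded cycle). This block-shape test is equivalent
to counting, per edge, the simple cycles through it (cycle edges lie in one
cycle, theta path-edges in two of the theta's three cycles) and is
linear-time. Triangle-freeness is tracked as a separate flag rather than
folded into the level, since the 1-nested class is triangle-free by
definition while for 2-nested networks it is an extra restriction.

The resistance distance between nodes `i, j` of a connected graph `G` with
`m` vertices is `Ω_ij = Γ⁻¹_ii + Γ⁻¹_jj − 2Γ⁻¹_ij` with `Γ = L + J/m`.
Two conventions had to be fixed:

* **`L` is the conductance Laplacian** (off-diagonal `−1/w(e)`). Unit-weight
  examples cannot distinguish this from using weights directly, but only
  conductances make `Ω` obey Ohm's series and parallel laws on weighted
  graphs, which is the whole point of the model.
* **`m` is the total vertex count** of the graph — leaves and internal
  nodes alike — not the taxon count.

Exact mode performs Gauss–Jordan elimination with partial pivoting over
`fractions.Fraction`, so printed rationals such as 8/3 and 23/9 for the
K₃,₃ counterexample are reproduced bit-exactly; float mode uses a dense
NumPy inverse and agrees with exact mode to ~1e−12 at the sizes used here.
Zero-weight edges are accepted structurally (they are legal weights) but
rejected by every resistance computation, which requires strict positivity.

An independent route, `series_parallel_resistance`, computes leaf-to-leaf
resistance with no linear algebra at all: the pairwise circuit `P_ij` (the
union of the biconnected blocks along the block-cut walk from `i` to `j`)
is a series of paths and cycles on a 1-nested network, so each cycle
contributes `(arc1·arc2)/(arc1+arc2)` and everything else adds. The two
routes are asserted equal on every random fixture; theta blocks raise, and
callers fall back to the Laplacian route.

## Kalmanson metrics and circular decomposition

A distance vector is Kalmanson when some circular order satisfies
`max{d_ij + d_kl, d_jk + d_il} ≤ d_ik + d_jl` for every quadruple taken as
a subsequence of the cyclic order (not only consecutive ones); ties count
as satisfying. Circular orders are canonicalized up to rotation **and
reflection** (smallest taxon first, smaller second neighbour), so sets of
orders compare exactly. This convention also makes the two definitions of
the BME vertex vector agree (see below): a cyclic order and its reflection
are the same adjacency structure and must not be counted twice.

Order search is exhaustive over the `(n−1)!/2` canonical orders with a
default bound of `n ≤ 9` and early abort on the first violated quadruple;
the first passing order in enumeration order is returned, making every
search deterministic. No agglomerative heuristic (e.g. neighbor-net) is
used anywhere: at desk scale the exhaustive search plus the classical
decomposition index is exact, which is what the bit-exact assertions need.

Given a Kalmanson order `c`, the unique weighted circular split system with
`d_s = d` is recovered by the split-decomposition index: the arc
`{c_i..c_j}` gets weight
`½·[d(c_{i−1},c_j) + d(c_i,c_{j+1}) − d(c_{i−1},c_{j+1}) − d(c_i,c_j)]`.
In exact mode a negative weight raises (the metric was not Kalmanson along
that order) and zero weights are dropped; in float mode the tolerance is
1e−9 for both. Decomposition output is *not* forced to contain trivial
splits — the unique system need not contain them — while split systems
declared as such always do.

## The maps between networks and split systems

`rw_direct` weights every displayed split of a 1-nested network by the sum
of its displays (`w(e)` per bridge display, `a·x/z` per cycle-pair
display); displays are enumerated by brute force over bridges and cycle
edge pairs and grouped by bipartition. Its split metric equals the
resistance vector exactly — that identity, asserted over all 200 random
rational-weighted fixtures, is the package's central invariant, and makes
`rw_metric` (decomposition of the measured metric) a redundant but
independent second route to the same object.

`L_exterior`/`lw` reconstruct the (weighted) exterior network from a
circular split system purely combinatorially, with no embedding: splits are
read as arcs of a circular order, arcs that pairwise cross (partially
overlap) are merged into crossing classes, each class of size ≥ 2 becomes a
cycle whose nodes are the sectors cut out by the class's arc boundaries,
singleton classes become bridges, trivial splits become leaf edges, and
items nest by arc inclusion (a bridge whose arc equals a class union wraps
that cycle). Edge weights follow the arc boundaries: a bridge or leaf edge
takes its split's weight; the cycle edge at a boundary position takes the
sum of the class splits with an arc boundary there. This attribution is
validated not by a construction proof but through the distance identities
it must satisfy: `L∘Σ` is the identity on fixtures (up to label-preserving
isomorphism), the unweighted image of `lw` equals `L` of the unweighted
system, and for outer-path systems the minimum-path metric of `lw(s)`
equals the split metric of `s`. For inputs violating those preconditions
the weights are implementation-defined.

`sw` projects the minimum-path metric; on 1-nested networks the consistent
orders are used directly, on 2-nested inputs a Kalmanson order is searched
for and `NotKalmansonError` is raised when none exists. Outer-path-ness is
decided by the operational criterion `d_{L_w(s)} = d_s`.

The marguerite of an `m`-cycle (`m ≥ 5`) is reported as counts
(`m²−4m` parallelograms, `m(m−5)` interior and `m(m−3)` exterior sides)
and optionally materialized as the ring-of-parallelograms graph: `m` rhombi
whose inner corners meet in a point when `m = 5` and are joined by rows of
`m−5` parallelograms otherwise, leaving exactly `m` degree-2 outer corners
for the pendant bridges.

## BME polytopes

The vertex vector of a binary 1-nested network is computed two ways:
summing adjacency incidence vectors over all consistent canonical orders,
and the closed form `x_ij = 2^(k−b_ij)` on pairs that can be adjacent in
some consistent order (0 otherwise). Here `k` and `b_ij` count
**non-trivial** bridges; trivial bridges contribute no twisting freedom,
and only this reading makes the two definitions agree. Adjacency of a pair
is decided structurally — on every cycle block of the walk between the two
leaves, entry and exit nodes must be adjacent on the cycle — keeping the
closed form independent of the order enumeration it is tested against.
Minimization of `x·d` is by exhaustive vertex enumeration with exact
rational dot products (no LP, no facet description).

Binary triangle-free 1-nested networks are enumerated by generating all
unrooted trees with internal degrees ≥ 3 (unique leaf-addition ancestry, so
no deduplication is needed), keeping those with exactly `k` internal edges,
and expanding every internal node of degree ≥ 4 into a cycle, one
neighbour per cycle node, arrangements counted up to rotation and
reflection. The counts match `C(n−3,k)·(n+k−1)!/(2k+2)!!` for all `n ≤ 6`.
The general (non-binary) enumerator additionally allows each high-degree
node to stay or to expand into shorter cycles with neighbours grouped onto
cycle nodes; it is exact for `n ≤ 5` (beyond that, configurations with two
cycles sharing a cut node appear, which the tree-expansion model does not
reach) and is used for the four-leaf census of seven displayed-split
classes.

## 2-nested enumeration

A chord joins new degree-3 midpoints subdividing two non-adjacent edges of
a cycle; subdividing is the only reading under which the result stays
simple, binary and triangle-free and a 4-cycle admits exactly two chords.
One cycle can carry at most one chord (a second would put an edge into
three cycles), but distinct cycle blocks are chorded independently: the
enumeration runs over every non-empty subset of cycle blocks of every
binary triangle-free 1-nested base, one placement per chosen cycle. Under
this model the counts are 6, 120 and 2790 for `n = 4, 5, 6`; restricting to
a single chord overall would undercount `n = 6` (the two-4-cycle exterior
contributes its doubly-chorded forms). Deduplication uses a
Weisfeiler–Lehman certificate over leaf-labelled graphs with exact
isomorphism checks inside certificate buckets; the construction is in fact
injective (bases are recovered by deleting the unique length-1 hub paths),
so the certificates also serve as a consistency check.

## Sequence-distance calibration

The Jukes–Cantor distance is used both as `D(p) = −(3/4)ln(1−4p/3)` and in
match-count form `D(c) = (3/4)ln(3m/(4c−m))`; saturation returns `inf`
explicitly. The Kimura two-parameter form is
`K = −½ln((1−2p−q)·sqrt(1−2q))`. The expected match count after a
recombination joining two equal parallel branches solves `D(c) = D(c1)/2`,
giving `c = m/4 + sqrt(3((m/4)c1 − (m/4)²))`; the closed form is unit-tested
against a numerical root-finder across the admissible range rather than
assumed, and `c` is returned unrounded.

## Random fixtures

Generators are pure functions of `(spec, seed)`. Weights are rationals
`p/q` with denominators ≤ 100 sampled uniformly in `[1, 10]` — large enough
to exercise non-trivial parallel combinations, small enough to keep exact
Gaussian elimination fast — precisely so that the theorem-level assertions
can demand bit-exact equality. Trees are grown by random leaf addition
(attachment probability 0.55 to an existing internal node), high-degree
nodes become cycles, and specs requesting a minimum cycle count resample
(still seeded) until satisfied. The standard pool is 200 networks with
`n = 5..8`, each with at least one cycle.

These fixtures emulate the combinatorial structure of reticulate
evolution, not its statistics: weights are i.i.d. rationals rather than
clock-like branch lengths, there is no measurement noise, and metrics are
exact. Passing tests therefore establish the mathematical identities on
the stated classes, not robustness of reconstruction under noisy distance
estimates — noisy-metric fitting is deliberately out of scope.

## Known limitations

* All order-dependent operations are exhaustive and bounded at `n ≤ 9`
  (configurable); the package is a desk-scale reference implementation, not
  a large-`n` tool.
* `enumerate_1nested` (the non-binary enumerator) is exact only for
  `n ≤ 5`, as noted above; the binary enumerators are bounded at `n ≤ 7`.
* `L_exterior`/`lw` assume a circular split system; non-circular inputs
  raise during arc extraction.
* Resistance on 2-nested networks is computed (the Laplacian route does not
  care about nestedness), but whether their resistance metrics are always
  Kalmanson is left open; the generators expose the question as a reportable
  fraction, and the K₃,₃ example shows the property fails eventually.
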