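"""Seeded generators of random weighted 1- and 2-nested networks and split
systems, plus the fixed non-Kalmanson counterexample.

Weights are positive rationals (p/q with bounded numerator and denominator),
sampled uniformly in [1, 10] by default, so the exact-arithmetic identities
(resistance = split metric of the direct construction, decomposition round
trips) can be asserted bit-exactly rather than to a tolerance.  All
generators are pure functions of their specification and seed.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from fractions import Fraction

import networkx as nx

from .network import CYCLE, PhyloNetwork, Split, cycle_blocks
from .splits import WeightedSplitSystem
from .twonested import chord_placements, insert_chord

__all__ = [
    "FixtureSpec",
    "random_1nested",
    "random_2nested",
    "random_weighted_circular_system",
    "k33_counterexample",
]


@dataclass(frozen=True)
class FixtureSpec:
    """What to generate: n leaves, how many cycles at least, weight range."""

    n: int
    seed: int
    min_cycles: int = 1
    weight_low: int = 1
    weight_high: int = 10
    denominator_bound: int = 100


def _random_weight(rng: random.Random, spec: FixtureSpec) -> Fraction:
    q = rng.randint(1, spec.denominator_bound)
    p = rng.randint(spec.weight_low * q, spec.weight_high * q)
    return Fraction(p, q)


def _random_tree(rng: random.Random, n: int, attach_prob: float) -> nx.Graph:
    """Random unrooted tree with internal degrees >= 3 by random leaf
    addition; higher attach_prob yields higher-degree internal nodes."""
    g = nx.Graph()
    g.add_edge("leaf1", "leaf2")
    for j in range(3, n + 1):
        leaf = f"leaf{j}"
        internals = [v for v in g.nodes if not str(v).startswith("leaf")]
        if internals and rng.random() < attach_prob:
            g.add_edge(rng.choice(sorted(internals)), leaf)
        else:
            u, v = sorted(g.edges())[rng.randrange(g.number_of_edges())]
            mid = f"i{j}"
            g.remove_edge(u, v)
            g.add_edge(u, mid)
            g.add_edge(mid, v)
            g.add_edge(mid, leaf)
    return g


def random_1nested(spec: FixtureSpec) -> PhyloNetwork:
    """Random binary triangle-free 1-nested network with positive rational
    weights; internal tree nodes of degree >= 4 become cycles.

    Resampling (still seeded) is used until the requested minimum number of
    cycles is present; infeasible requests raise after a bounded number of
    attempts.
    """
    if spec.n < 3 and spec.min_cycles > 0:
        raise ValueError("cycles need at least 3 leaves")
    rng = random.Random(spec.seed)
    for _ in range(300):
        tree = _random_tree(rng, spec.n, attach_prob=0.55)
        big = [v for v in tree.nodes if not str(v).startswith("leaf") and tree.degree(v) >= 4]
        if len(big) < spec.min_cycles:
            continue
        port = {}
        cyc_edges = []
        for v in big:
            nbrs = sorted(tree.neighbors(v), key=str)
            rng.shuffle(nbrs)
            m = len(nbrs)
            cyc = [f"c{v}.{i}" for i in range(m)]
            for i, u in enumerate(nbrs):
                port[(v, u)] = cyc[i]
                cyc_edges.append((cyc[i], cyc[(i + 1) % m]))
        g = nx.Graph()
        bigset = set(big)
        for u1, u2 in tree.edges():
            a = port[(u1, u2)] if u1 in bigset else u1
            b = port[(u2, u1)] if u2 in bigset else u2
            g.add_edge(a, b)
        g.add_edges_from(cyc_edges)
        for u, v in g.edges():
            g.edges[u, v]["weight"] = _random_weight(rng, spec)
        leaves = {i: f"leaf{i}" for i in range(1, spec.n + 1)}
        return PhyloNetwork(g, leaves)
    raise ValueError(f"could not generate a network with {spec.min_cycles} cycles for n={spec.n}")


def random_2nested(spec: FixtureSpec) -> PhyloNetwork:
    """Random strictly 2-nested binary triangle-free network: a random
    1-nested base with a randomly placed, randomly weighted chord."""
    base = random_1nested(spec)
    rng = random.Random(spec.seed + 0x2E)
    blocks = [b for b in cycle_blocks(base) if b.kind == CYCLE]
    block = blocks[rng.randrange(len(blocks))]
    placements = chord_placements(len(block.nodes))
    pair = placements[rng.randrange(len(placements))]
    return insert_chord(base, block, pair, chord_weight=_random_weight(rng, spec))


def random_weighted_circular_system(spec: FixtureSpec) -> WeightedSplitSystem:
    """Random weighted circular split system: random contiguous arcs of the
    identity circular order (plus all trivial splits), rational weights."""
    rng = random.Random(spec.seed)
    n = spec.n
    weights = {}
    for i in range(1, n + 1):
        weights[Split.trivial(i, n)] = _random_weight(rng, spec)
    universe = list(range(1, n + 1))
    n_extra = rng.randint(1, max(1, n - 2))
    for _ in range(n_extra):
        start = rng.randrange(n)
        length = rng.randint(2, n - 2)
        side = frozenset(universe[(start + t) % n] for t in range(length))
        sp = Split.of(side, set(universe) - side)
        if sp.is_trivial or sp in weights:
            continue
        weights[sp] = _random_weight(rng, spec)
    return WeightedSplitSystem.of(n, weights)


def k33_counterexample() -> PhyloNetwork:
    """Six unit-weight leaves pendant on the complete bipartite graph K_3,3
    with unit edges: a phylogenetic network whose resistance distance is not
    Kalmanson (leaves 1-3 on one part, 4-6 on the other)."""
    g = nx.Graph()
    reds = [f"r{i}" for i in range(3)]
    blues = [f"b{i}" for i in range(3)]
    for r in reds:
        for b in blues:
            g.add_edge(r, b, weight=Fraction(1))
    leaves = {}
    for i, r in enumerate(reds, start=1):
        g.add_edge(f"leaf{i}", r, weight=Fraction(1))
        leaves[i] = f"leaf{i}"
    for i, b in enumerate(blues, start=4):
        g.add_edge(f"leaf{i}", b, weight=Fraction(1))
        leaves[i] = f"leaf{i}"
    return PhyloNetwork(g, leaves)
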