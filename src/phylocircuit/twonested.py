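"""Binary triangle-free 2-nested networks: chord insertion and enumeration.

A 2-nested network has every edge in at most two cycles; the strict ones are
obtained from 1-nested networks by adding internal chords.  A chord joins
subdivision midpoints of two non-adjacent edges of a cycle (subdividing each
with a new degree-3 node), which is the only insertion under which the
result stays binary and triangle-free.  Each cycle block can carry at most
one chord (a second chord in the same cycle puts some edge into more than
two cycles), but different cycle blocks may be chorded independently.

Enumerating one chord per cycle over every non-empty subset of cycle blocks
of every binary triangle-free 1-nested base reproduces the counts
6, 120, 2790 for n = 4, 5, 6.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import networkx as nx

from .bme import enumerate_binary_1nested
from .distance import min_path_vector
from .isomorphism import dedupe
from .network import (
    Block,
    NetworkError,
    PhyloNetwork,
    cycle_blocks,
    is_binary,
    nestedness_level,
)

__all__ = [
    "chord_placements",
    "insert_chord",
    "enumerate_2nested",
    "count_2nested",
    "match_minpath_1nested",
]


def chord_placements(m: int) -> list:
    """Unordered pairs of distinct non-adjacent edge indices of an m-cycle
    (edge i joins cycle nodes i and i+1 mod m); there are m(m-3)/2 pairs."""
    if m < 4:
        raise ValueError("chords require a cycle of length >= 4")
    out = []
    for i in range(m):
        for j in range(i + 2, m):
            if i == 0 and j == m - 1:
                continue
            out.append((i, j))
    return out


def _block_cycle_nodes(net: PhyloNetwork, block: Block) -> list:
    sub = net.graph.subgraph(block.nodes)
    if any(d != 2 for _, d in sub.degree()):
        raise NetworkError(["chords can only be inserted into simple cycle blocks"])
    return nx.cycle_basis(sub)[0]


def insert_chord(
    net: PhyloNetwork,
    block: Block,
    pair: tuple,
    chord_weight=Fraction(1),
    tag: str = "",
) -> PhyloNetwork:
    """Insert one chord into a cycle block: subdivide the two chosen edges at
    new degree-3 midpoints and join the midpoints.

    The two subdivided halves each keep half of the original edge weight.
    Adjacent edge pairs are rejected (the chord would close a triangle).
    """
    cyc = _block_cycle_nodes(net, block)
    m = len(cyc)
    i, j = pair
    if i == j or (abs(i - j) in (1, m - 1)):
        raise ValueError("chord endpoints must be non-adjacent cycle edges")
    g = net.graph.copy()
    mids = []
    for t, e in enumerate((i, j)):
        u, v = cyc[e], cyc[(e + 1) % m]
        w = g.edges[u, v]["weight"]
        mid = f"x{tag}.{t}"
        g.remove_edge(u, v)
        g.add_edge(u, mid, weight=w / 2)
        g.add_edge(mid, v, weight=w / 2)
        mids.append(mid)
    g.add_edge(mids[0], mids[1], weight=chord_weight)
    return PhyloNetwork(g, net.leaves)


def _all_chordings(net: PhyloNetwork) -> list:
    """Every network from chording a non-empty subset of cycle blocks, one
    chord per chosen cycle."""
    blocks = [b for b in cycle_blocks(net) if b.kind == "CYCLE"]
    options = []
    for bi, block in enumerate(blocks):
        m = len(block.nodes)
        options.append([None] + [(block, p) for p in chord_placements(m)])
    out = []
    for combo in itertools.product(*options):
        chosen = [c for c in combo if c is not None]
        if not chosen:
            continue
        result = net
        for t, (block, pair) in enumerate(chosen):
            result = insert_chord(result, block, pair, tag=f"{t}")
        out.append(result)
    return out


def enumerate_2nested(n: int, bound: int = 7) -> list:
    """All binary triangle-free strictly 2-nested networks with n labeled
    leaves obtainable by chord insertion, up to isomorphism fixing leaf
    labels."""
    if not 4 <= n <= bound:
        raise ValueError(f"supported range is 4 <= n <= {bound}")
    chorded = []
    for k in range(0, n - 2):
        if k > n - 3:
            continue
        for base in enumerate_binary_1nested(n, k):
            chorded.extend(_all_chordings(base))
    return dedupe(chorded)


def count_2nested(n: int, bound: int = 7) -> int:
    """Number of binary triangle-free strictly 2-nested networks with n
    labeled leaves (6, 120, 2790 for n = 4, 5, 6)."""
    return len(enumerate_2nested(n, bound=bound))


def match_minpath_1nested(net: PhyloNetwork) -> PhyloNetwork:
    """A weighted 2-nested network with the same minimum path distance vector
    as the given 1-nested network: insert a chord heavier than the total edge
    weight into the first cycle, so no shortest path ever uses it."""
    if nestedness_level(net).level != 1:
        raise NetworkError(["requires a 1-nested network with at least one cycle"])
    blocks = [b for b in cycle_blocks(net) if b.kind == "CYCLE"]
    block = blocks[0]
    heavy = net.total_weight + 1
    chorded = insert_chord(net, block, chord_placements(len(block.nodes))[0], chord_weight=heavy)
    assert min_path_vector(chorded).values == min_path_vector(net).values
    return chorded
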