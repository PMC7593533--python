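"""Balanced minimum evolution polytopes for level-1 networks: BME(n, k).

The vertices of BME(n, k) are the vectors x(N) of unweighted binary 1-nested
networks N with n leaves and k non-trivial bridges.  Two equivalent
definitions are implemented and cross-checked:

* ``bme_vector_orders``: x(N) is the sum of the adjacency incidence vectors
  x(c) over all circular leaf orders c consistent with N (orders taken up to
  rotation and reflection);
* ``bme_vector_formula``: x_ij(N) = 2^(k - b_ij) when i and j can be adjacent
  in a consistent order and 0 otherwise, where b_ij counts the non-trivial
  bridges separating i from j.

Minimizing the linear functional x . d over the vertices of BME(n, k) with d
a resistance distance vector performs balanced-minimum-evolution selection of
the generating network class.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from typing import Iterable, Sequence

import networkx as nx

from .distance import DistanceVector, lex_pairs
from .isomorphism import dedupe
from .network import (
    CYCLE,
    PhyloNetwork,
    consistent_orders,
    cycle_blocks,
    find_bridges,
    is_binary,
    nestedness_level,
    sigma_splits,
)

__all__ = [
    "BMEVector",
    "bme_vector_orders",
    "bme_vector_formula",
    "count_binary_1nested",
    "enumerate_binary_1nested",
    "enumerate_1nested",
    "bme_functional",
    "minimize_over_vertices",
    "refines",
]


class BMEVector(tuple):
    """x(N): lexicographically ordered integer components x_ij, i < j."""

    def __new__(cls, n: int, values: Sequence[int]):
        if len(values) != n * (n - 1) // 2:
            raise ValueError("wrong number of components")
        obj = super().__new__(cls, values)
        obj.n = n
        return obj

    def get(self, i: int, j: int) -> int:
        if i > j:
            i, j = j, i
        return self[(i - 1) * (2 * self.n - i) // 2 + (j - i - 1)]


def bme_vector_orders(net: PhyloNetwork, bound: int = 9) -> BMEVector:
    """x(N) as the sum of incidence vectors of all consistent circular
    orders: x_ij = number of consistent orders with i and j adjacent."""
    orders = consistent_orders(net, bound=bound)
    counts = {p: 0 for p in lex_pairs(net.n)}
    for order in orders:
        for p in order.adjacent_pairs():
            counts[p] += 1
    return BMEVector(net.n, [counts[p] for p in lex_pairs(net.n)])


def _cycle_entry_exit_adjacent(net: PhyloNetwork, i: int, j: int) -> bool:
    """True if on every cycle block of the walk from i to j, the entry and
    exit nodes are adjacent on the cycle (the structural condition for i, j
    to be adjacent in some consistent circular order)."""
    from .distance import _block_cut_path

    for comp, entry, exit_ in _block_cut_path(net, i, j):
        sub = net.graph.subgraph(comp)
        if sub.number_of_edges() == 1:
            continue
        if not sub.has_edge(entry, exit_):
            return False
    return True


def bme_vector_formula(net: PhyloNetwork) -> BMEVector:
    """Closed-form x(N) for a binary 1-nested network: 2^(k - b_ij) on pairs
    that can be adjacent in a consistent order, 0 elsewhere."""
    if not is_binary(net):
        raise ValueError("the closed-form vector requires a binary network")
    if nestedness_level(net).level > 1:
        raise ValueError("the closed-form vector requires a 1-nested network")
    nontrivial = [b for b in find_bridges(net) if not b.is_trivial]
    k = len(nontrivial)
    values = []
    for i, j in lex_pairs(net.n):
        if _cycle_entry_exit_adjacent(net, i, j):
            b_ij = sum(1 for b in nontrivial if b.split.separates(i, j))
            values.append(2 ** (k - b_ij))
        else:
            values.append(0)
    return BMEVector(net.n, values)


# ---------------------------------------------------------------------------
# counting and enumeration of binary triangle-free 1-nested networks
# ---------------------------------------------------------------------------


def _double_factorial(m: int) -> int:
    out = 1
    while m > 1:
        out *= m
        m -= 2
    return out


def count_binary_1nested(n: int, k: int) -> int:
    """Closed-form count of binary triangle-free 1-nested networks with n
    labeled leaves and k non-trivial bridges:
    C(n-3, k) * (n+k-1)! / (2k+2)!!."""
    if not 0 <= k <= n - 3:
        raise ValueError(f"k must satisfy 0 <= k <= n-3; got n={n}, k={k}")
    import math

    return math.comb(n - 3, k) * math.factorial(n + k - 1) // _double_factorial(2 * k + 2)


def _trees_min_deg3(n: int) -> list:
    """All unrooted trees on leaves 1..n with unlabeled internal nodes of
    degree >= 3, as networkx graphs with leaf nodes named ``leaf<i>``.

    Leaf-addition enumeration: every such tree on j+1 leaves arises exactly
    once by removing the leaf j+1 from its parent tree.
    """
    if n < 2:
        raise ValueError("need at least two leaves")
    base = nx.Graph()
    base.add_edge("leaf1", "leaf2")
    trees = [base]
    for j in range(3, n + 1):
        leaf = f"leaf{j}"
        new = []
        for t in trees:
            for u, v in list(t.edges()):
                t2 = t.copy()
                mid = f"i{j}.{len(new)}"
                t2.remove_edge(u, v)
                t2.add_edge(u, mid)
                t2.add_edge(mid, v)
                t2.add_edge(mid, leaf)
                new.append(t2)
            for u in t.nodes():
                if not str(u).startswith("leaf"):
                    t2 = t.copy()
                    t2.add_edge(u, leaf)
                    new.append(t2)
        trees = new
    return trees


def _cyclic_arrangements(parts: Sequence) -> list:
    """Distinct cyclic sequences of the given distinct parts, up to rotation
    and reflection: (len-1)!/2 of them (or 1 when len <= 2)."""
    parts = sorted(parts, key=str)
    first, rest = parts[0], parts[1:]
    if len(parts) <= 3:
        return [tuple(parts)]
    out = []
    for perm in itertools.permutations(rest):
        if perm[0] < perm[-1]:
            out.append((first,) + perm)
    return out


def _expand_tree(tree: nx.Graph, expansions: dict) -> nx.Graph:
    """Replace each tree node v in ``expansions`` by a cycle; the value is
    the cyclic sequence of groups of v's neighbours, one group per cycle
    node.  Neighbour stubs are rewired to the cycle node owning them."""
    port = {}
    cyc_edges = []
    for v, groups in expansions.items():
        m = len(groups)
        cyc = [f"c{v}.{i}" for i in range(m)]
        for i, group in enumerate(groups):
            for u in group:
                port[(v, u)] = cyc[i]
            cyc_edges.append((cyc[i], cyc[(i + 1) % m]))
    g = nx.Graph()
    expanded = set(expansions)
    for u1, u2 in tree.edges():
        a = port[(u1, u2)] if u1 in expanded else u1
        b = port[(u2, u1)] if u2 in expanded else u2
        g.add_edge(a, b)
    g.add_edges_from(cyc_edges)
    return g


def _as_network(g: nx.Graph, n: int) -> PhyloNetwork:
    leaves = {i: f"leaf{i}" for i in range(1, n + 1)}
    for u, v in g.edges():
        g.edges[u, v]["weight"] = Fraction(1)
    return PhyloNetwork(g, leaves)


def enumerate_binary_1nested(n: int, k: int, bound: int = 7) -> list:
    """All binary triangle-free 1-nested networks with n labeled leaves and
    exactly k non-trivial bridges, up to isomorphism fixing leaf labels.

    Construction: unrooted trees with internal degrees >= 3 and exactly k
    internal edges; every internal node of degree >= 4 is expanded into a
    cycle, one neighbour per cycle node, arrangements counted up to rotation
    and reflection.  The count matches :func:`count_binary_1nested`.
    """
    if n > bound:
        raise ValueError(f"enumeration bound exceeded: n={n} > {bound}")
    if not 0 <= k <= n - 3:
        return []
    out = []
    for tree in _trees_min_deg3(n):
        internals = [v for v in tree.nodes if not str(v).startswith("leaf")]
        internal_edges = sum(
            1
            for u, v in tree.edges()
            if not str(u).startswith("leaf") and not str(v).startswith("leaf")
        )
        if internal_edges != k:
            continue
        big = [v for v in internals if tree.degree(v) >= 4]
        arrangement_sets = [
            [
                tuple((u,) for u in arr)
                for arr in _cyclic_arrangements(list(tree.neighbors(v)))
            ]
            for v in big
        ]
        for combo in itertools.product(*arrangement_sets):
            g = _expand_tree(tree, dict(zip(big, combo)))
            out.append(_as_network(g, n))
    return out


def enumerate_1nested(n: int, bound: int = 5) -> list:
    """All (not necessarily binary) triangle-free 1-nested networks on n
    labeled leaves, up to isomorphism fixing leaf labels.

    Internal nodes of degree d >= 4 may stay or be expanded into a cycle of
    length 4..d with the d incident parts grouped onto cycle nodes (every
    cycle node holding at least one part).  Restricted to small n: for
    n <= 5 every 1-nested network arises this way from a unique tree.
    """
    if n > bound:
        raise ValueError(f"enumeration bound exceeded: n={n} > {bound}")
    out = []
    for tree in _trees_min_deg3(n):
        internals = [v for v in tree.nodes if not str(v).startswith("leaf")]
        big = [v for v in internals if tree.degree(v) >= 4]
        per_node_options = []
        for v in big:
            nbrs = sorted(tree.neighbors(v), key=str)
            options = [None]  # keep the node as-is
            for m in range(4, len(nbrs) + 1):
                options.extend(_grouped_cyclic_arrangements(nbrs, m))
            per_node_options.append(options)
        for combo in itertools.product(*per_node_options):
            expansions = {v: c for v, c in zip(big, combo) if c is not None}
            g = _expand_tree(tree, expansions) if expansions else tree.copy()
            out.append(_as_network(g, n))
    return dedupe(out)


def _grouped_cyclic_arrangements(parts: Sequence, m: int) -> list:
    """Cyclic sequences of m disjoint non-empty groups covering ``parts``,
    up to rotation and reflection."""
    parts = list(parts)
    results = set()
    for assignment in itertools.product(range(m), repeat=len(parts)):
        groups = [tuple(sorted((p for p, a in zip(parts, assignment) if a == i), key=str)) for i in range(m)]
        if any(not gp for gp in groups):
            continue
        results.add(_canonical_cycle(tuple(groups)))
    return sorted(results)


def _canonical_cycle(groups: tuple) -> tuple:
    m = len(groups)
    candidates = []
    for seq in (groups, tuple(reversed(groups))):
        for r in range(m):
            candidates.append(seq[r:] + seq[:r])
    return min(candidates)


# ---------------------------------------------------------------------------
# the linear functional and its minimization
# ---------------------------------------------------------------------------


def bme_functional(x: BMEVector, d: DistanceVector):
    """The linear functional x(N) . d."""
    if x.n != d.n:
        raise ValueError("dimension mismatch")
    return sum(a * b for a, b in zip(x, d.values))


def minimize_over_vertices(d: DistanceVector, n: int, k: int, tol=0) -> list:
    """All vertex networks of BME(n, k) achieving the minimal value of
    x(N) . d.  Exhaustive over the enumerated vertices; deterministic."""
    vertices = enumerate_binary_1nested(n, k)
    scored = [(bme_functional(bme_vector_formula(v), d), v) for v in vertices]
    best = min(s for s, _ in scored)
    return [v for s, v in scored if s <= best + (tol or 0)]


def refines(a: PhyloNetwork, b: PhyloNetwork) -> bool:
    """True when every split displayed by B is displayed by A (A >= B)."""
    if set(a.leaves) != set(b.leaves):
        raise ValueError("networks have different leaf sets")
    return sigma_splits(b).splits <= sigma_splits(a).splits
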