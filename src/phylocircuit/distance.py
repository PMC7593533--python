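"""Distances on phylogenetic networks: effective resistance and minimum path.

Edge weights are read as electrical resistances.  The resistance distance
between two nodes of a connected graph ``G`` with ``n`` vertices is

    Omega_ij = Gamma^{-1}_ii + Gamma^{-1}_jj - 2 Gamma^{-1}_ij,

where ``Gamma = L + J/n``, ``L`` the (conductance) Laplacian of ``G`` and
``J`` the all-ones matrix.  The Laplacian of a resistance-weighted graph has
off-diagonal entries ``-1/w(e)``: unit-weight examples cannot distinguish the
conventions, but only conductances make Omega agree with Ohm's law for
series and parallel resistors on weighted graphs.

Exact mode does all arithmetic over :class:`fractions.Fraction`, so printed
rational resistances are reproduced bit-exactly; float mode uses a dense
NumPy solve.  A second, matrix-free route (:func:`series_parallel_resistance`)
reduces the pairwise circuit between two leaves by series/parallel steps and
serves as an independent oracle for the Laplacian route.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Hashable, Iterable, Sequence

import networkx as nx
import numpy as np

from .network import (
    CircularOrder,
    NetworkError,
    PhyloNetwork,
    canonical_order_candidates,
)

__all__ = [
    "DistanceVector",
    "ResistanceMatrix",
    "resistance_matrix",
    "resistance_leaf_vector",
    "min_path_vector",
    "wye_delta",
    "delta_wye",
    "series_parallel_resistance",
    "pairwise_circuit",
    "is_kalmanson",
    "find_kalmanson_order",
    "lex_pairs",
]


def lex_pairs(n: int) -> list:
    """Unordered taxon pairs (i, j), i < j, in lexicographic order."""
    return [(i, j) for i in range(1, n + 1) for j in range(i + 1, n + 1)]


@dataclass(frozen=True)
class DistanceVector:
    """Lexicographically listed leaf-pair distances d_ij, i < j."""

    n: int
    values: tuple

    def __post_init__(self):
        expect = self.n * (self.n - 1) // 2
        if len(self.values) != expect:
            raise ValueError(f"expected {expect} entries for n={self.n}, got {len(self.values)}")

    @staticmethod
    def from_function(n: int, f) -> "DistanceVector":
        return DistanceVector(n, tuple(f(i, j) for i, j in lex_pairs(n)))

    def get(self, i: int, j: int):
        if i == j:
            return 0
        if i > j:
            i, j = j, i
        idx = (i - 1) * (2 * self.n - i) // 2 + (j - i - 1)
        return self.values[idx]

    def as_array(self) -> np.ndarray:
        return np.array([float(v) for v in self.values])

    def almost_equal(self, other: "DistanceVector", tol: float = 1e-9) -> bool:
        if self.n != other.n:
            return False
        return all(abs(float(a) - float(b)) <= tol for a, b in zip(self.values, other.values))

    def __iter__(self):
        return iter(self.values)


# ---------------------------------------------------------------------------
# exact rational linear algebra (Gauss-Jordan with partial pivoting)
# ---------------------------------------------------------------------------


def _invert_rational(mat: Sequence[Sequence[Fraction]]) -> list:
    n = len(mat)
    aug = [list(row) + [Fraction(int(i == j)) for j in range(n)] for i, row in enumerate(mat)]
    for col in range(n):
        piv = next((r for r in range(col, n) if aug[r][col] != 0), None)
        if piv is None:
            raise ValueError("singular matrix")
        aug[col], aug[piv] = aug[piv], aug[col]
        inv_p = 1 / aug[col][col]
        aug[col] = [x * inv_p for x in aug[col]]
        for r in range(n):
            if r != col and aug[r][col] != 0:
                factor = aug[r][col]
                aug[r] = [a - factor * b for a, b in zip(aug[r], aug[col])]
    return [row[n:] for row in aug]


@dataclass(frozen=True)
class ResistanceMatrix:
    """Effective resistances Omega over all nodes of a network."""

    nodes: tuple
    omega: tuple  # row-major square matrix

    def get(self, u: Hashable, v: Hashable):
        i, j = self.nodes.index(u), self.nodes.index(v)
        return self.omega[i][j]


def _edge_weights_positive(net: PhyloNetwork):
    for u, v, data in net.graph.edges(data=True):
        if not data["weight"] > 0:
            raise NetworkError(
                [f"resistance requires strictly positive weights; edge ({u!r},{v!r}) has {data['weight']}"]
            )


def resistance_matrix(net: PhyloNetwork, mode: str = "exact") -> ResistanceMatrix:
    """Omega for all nodes, via Gamma = L + J/n with the conductance Laplacian.

    ``n`` here is the total number of vertices of the graph, leaves and
    internal nodes alike.
    """
    _edge_weights_positive(net)
    nodes = tuple(sorted(net.graph.nodes, key=str))
    idx = {v: i for i, v in enumerate(nodes)}
    m = len(nodes)
    if mode == "exact":
        gamma = [[Fraction(1, m) for _ in range(m)] for _ in range(m)]
        for u, v, data in net.graph.edges(data=True):
            c = 1 / Fraction(data["weight"])
            i, j = idx[u], idx[v]
            gamma[i][i] += c
            gamma[j][j] += c
            gamma[i][j] -= c
            gamma[j][i] -= c
        ginv = _invert_rational(gamma)
    elif mode == "float":
        gamma = np.full((m, m), 1.0 / m)
        for u, v, data in net.graph.edges(data=True):
            c = 1.0 / float(data["weight"])
            i, j = idx[u], idx[v]
            gamma[i, i] += c
            gamma[j, j] += c
            gamma[i, j] -= c
            gamma[j, i] -= c
        ginv = np.linalg.inv(gamma)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    omega = tuple(
        tuple(ginv[i][i] + ginv[j][j] - 2 * ginv[i][j] for j in range(m))
        for i in range(m)
    )
    return ResistanceMatrix(nodes, omega)


def resistance_leaf_vector(net: PhyloNetwork, mode: str = "exact") -> DistanceVector:
    """Restriction of Omega to the labelled leaves, lexicographic order."""
    rm = resistance_matrix(net, mode=mode)
    idx = {v: i for i, v in enumerate(rm.nodes)}
    leaf_idx = {lab: idx[node] for lab, node in net.leaves.items()}
    return DistanceVector.from_function(
        net.n, lambda i, j: rm.omega[leaf_idx[i]][leaf_idx[j]]
    )


def min_path_vector(net: PhyloNetwork) -> DistanceVector:
    """Shortest weighted path distance between each leaf pair."""
    dists = {}
    for lab, node in net.leaves.items():
        dists[lab] = nx.single_source_dijkstra_path_length(net.graph, node, weight="weight")
    return DistanceVector.from_function(net.n, lambda i, j: dists[i][net.leaves[j]])


# ---------------------------------------------------------------------------
# series / parallel reduction and the Y-Delta transform
# ---------------------------------------------------------------------------


def wye_delta(r1, r2, r3):
    """Star resistances (Ra, Rb, Rc) equivalent to a triangle (R1, R2, R3).

    Ra = R1 R2 / (R1+R2+R3) and cyclically.  Each star arm belongs to the
    triangle corner shared by the two edges in its numerator: Ra to the
    corner joining R1 and R2, Rb to R2/R3, Rc to R1/R3.  Substituting the
    star for the triangle leaves all pairwise resistances among the
    remaining nodes unchanged.
    """
    if not (r1 > 0 and r2 > 0 and r3 > 0):
        raise ValueError("triangle resistances must be positive")
    z = r1 + r2 + r3
    return (r1 * r2 / z, r2 * r3 / z, r1 * r3 / z)


def delta_wye(ra, rb, rc):
    """Inverse of :func:`wye_delta`: triangle equivalent to a 3-edge star."""
    if not (ra > 0 and rb > 0 and rc > 0):
        raise ValueError("star resistances must be positive")
    p = ra * rb + rb * rc + rc * ra
    return (p / rb, p / rc, p / ra)


def _block_cut_path(net: PhyloNetwork, i: int, j: int) -> list:
    """Blocks (as edge sets) along the walk from leaf i to leaf j, each with
    its entry and exit node."""
    g = net.graph
    src, dst = net.leaves[i], net.leaves[j]
    comps = list(nx.biconnected_components(g))
    arts = set(nx.articulation_points(g))
    bct = nx.Graph()
    for bi, comp in enumerate(comps):
        bct.add_node(("B", bi))
        for v in comp:
            if v in arts:
                bct.add_edge(("B", bi), ("A", v))
    def locate(v):
        if v in arts:
            return ("A", v)
        for bi, comp in enumerate(comps):
            if v in comp:
                return ("B", bi)
        raise KeyError(v)
    path = nx.shortest_path(bct, locate(src), locate(dst))
    out = []
    prev_cut = src
    for k, nd in enumerate(path):
        if nd[0] != "B":
            continue
        comp = comps[nd[1]]
        nxt_cut = dst if k == len(path) - 1 else path[k + 1][1]
        out.append((comp, prev_cut, nxt_cut))
        prev_cut = nxt_cut
    return out


def pairwise_circuit(net: PhyloNetwork, i: int, j: int) -> frozenset:
    """Edges lying on some path between leaves i and j (the pairwise circuit
    P_ij): the union of the biconnected blocks along the block-cut walk."""
    edges = set()
    for comp, _, _ in _block_cut_path(net, i, j):
        sub = net.graph.subgraph(comp)
        edges.update(frozenset(e) for e in sub.edges())
    return frozenset(edges)


def series_parallel_resistance(net: PhyloNetwork, i: int, j: int):
    """Effective resistance between leaves i and j by series/parallel
    reduction of the pairwise circuit, without any matrix inversion.

    Works whenever P_ij is a series of paths and simple cycles -- always the
    case on 1-nested networks.  Raises on blocks that are not single edges or
    simple cycles (e.g. theta blocks).
    """
    _edge_weights_positive(net)
    total = Fraction(0) if all(
        isinstance(d["weight"], (Fraction, int)) for _, _, d in net.graph.edges(data=True)
    ) else 0.0
    for comp, entry, exit_ in _block_cut_path(net, i, j):
        sub = net.graph.subgraph(comp)
        if sub.number_of_edges() == 1:
            ((u, v, data),) = sub.edges(data=True)
            total += data["weight"]
            continue
        degs = set(dict(sub.degree()).values())
        if degs != {2}:
            raise NetworkError(
                [f"pairwise circuit between {i} and {j} contains a non-series-reducible block"]
            )
        cyc = nx.cycle_basis(sub)[0]
        m = len(cyc)
        pos_entry, pos_exit = cyc.index(entry), cyc.index(exit_)
        arc1 = 0
        k = pos_entry
        while k != pos_exit:
            nxt = (k + 1) % m
            arc1 += sub.edges[cyc[k], cyc[nxt]]["weight"]
            k = nxt
        arc2 = 0
        k = pos_exit
        while k != pos_entry:
            nxt = (k + 1) % m
            arc2 += sub.edges[cyc[k], cyc[nxt]]["weight"]
            k = nxt
        total += arc1 * arc2 / (arc1 + arc2)
    return total


# ---------------------------------------------------------------------------
# the Kalmanson condition
# ---------------------------------------------------------------------------


def is_kalmanson(d: DistanceVector, order: CircularOrder, tol=0):
    """Check the four-point condition for every 4-subsequence of the cyclic
    order:  max{d_ij + d_kl, d_jk + d_il} <= d_ik + d_jl.

    Ties count as satisfying.  Returns ``(ok, violations)`` where violations
    is a list of offending taxon quadruples (i, j, k, l).
    """
    seq = tuple(order)
    violations = []
    for a, b, c, e in itertools.combinations(range(len(seq)), 4):
        i, j, k, l = seq[a], seq[b], seq[c], seq[e]
        rhs = d.get(i, k) + d.get(j, l)
        if d.get(i, j) + d.get(k, l) > rhs + tol or d.get(j, k) + d.get(i, l) > rhs + tol:
            violations.append((i, j, k, l))
    return (not violations, violations)


def _kalmanson_fast(d: DistanceVector, order: CircularOrder, tol=0) -> bool:
    seq = tuple(order)
    get = d.get
    for a, b, c, e in itertools.combinations(range(len(seq)), 4):
        i, j, k, l = seq[a], seq[b], seq[c], seq[e]
        rhs = get(i, k) + get(j, l) + tol
        if get(i, j) + get(k, l) > rhs or get(j, k) + get(i, l) > rhs:
            return False
    return True


def find_kalmanson_order(d: DistanceVector, bound: int = 9, tol=0):
    """First canonical circular order (in enumeration order) for which d is
    Kalmanson, or None.  Exhaustive and deterministic."""
    if d.n > bound:
        raise ValueError(f"order search bound exceeded: n={d.n} > {bound}")
    for order in canonical_order_candidates(d.n):
        if _kalmanson_fast(d, order, tol=tol):
            return order
    return None
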