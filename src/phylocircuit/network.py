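"""Unrooted phylogenetic networks as weighted graphs.

A phylogenetic network on the taxon set ``[n] = {1, ..., n}`` is a simple
connected graph whose degree-1 vertices (the leaves) are labelled bijectively
by ``[n]`` and whose unlabelled vertices all have degree at least 3.  Edge
weights are non-negative and are read as resistances by the distance layer.

The structural vocabulary lives here: bridges, cycle blocks (biconnected
components that are simple cycles), theta blocks (chorded cycles), nestedness
level, the displayed split system Sigma, and the circular leaf orders
consistent with a network.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from typing import Any, Hashable, Iterable, Iterator, Mapping, Sequence

import networkx as nx

__all__ = [
    "NetworkError",
    "PhyloNetwork",
    "Split",
    "SplitSystem",
    "CircularOrder",
    "Bridge",
    "Block",
    "Nestedness",
    "validate_network",
    "find_bridges",
    "cycle_blocks",
    "nestedness_level",
    "is_binary",
    "sigma_splits",
    "split_equivalent",
    "consistent_orders",
    "orders_of_system",
    "canonical_order_candidates",
]

CYCLE = "CYCLE"
THETA = "THETA"
OTHER = "OTHER"


class NetworkError(ValueError):
    """Raised when a graph violates the phylogenetic-network invariants."""

    def __init__(self, diagnostics: Sequence[str]):
        self.diagnostics = list(diagnostics)
        super().__init__("; ".join(self.diagnostics))


# ---------------------------------------------------------------------------
# splits and circular orders
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Split:
    """An unordered bipartition A|B of the taxon set.

    Canonical form stores the side containing the smallest taxon as
    ``part_a``, so equality and hashing behave as for unordered pairs.
    """

    part_a: frozenset
    part_b: frozenset

    @staticmethod
    def of(a: Iterable[int], b: Iterable[int]) -> "Split":
        fa, fb = frozenset(a), frozenset(b)
        if not fa or not fb:
            raise ValueError("both parts of a split must be non-empty")
        if fa & fb:
            raise ValueError("split parts must be disjoint")
        if min(fa) > min(fb):
            fa, fb = fb, fa
        return Split(fa, fb)

    @staticmethod
    def trivial(i: int, n: int) -> "Split":
        return Split.of({i}, set(range(1, n + 1)) - {i})

    @property
    def n(self) -> int:
        return len(self.part_a) + len(self.part_b)

    @property
    def is_trivial(self) -> bool:
        return min(len(self.part_a), len(self.part_b)) == 1

    def separates(self, i: int, j: int) -> bool:
        return (i in self.part_a) != (j in self.part_a)

    def side_without(self, t: int) -> frozenset:
        return self.part_b if t in self.part_a else self.part_a

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        a = ",".join(map(str, sorted(self.part_a)))
        b = ",".join(map(str, sorted(self.part_b)))
        return f"{{{a}}}|{{{b}}}"


@dataclass(frozen=True)
class SplitSystem:
    """A set of splits of [n] containing all n trivial splits."""

    n: int
    splits: frozenset

    @staticmethod
    def of(n: int, splits: Iterable[Split], add_trivial: bool = True) -> "SplitSystem":
        s = set(splits)
        if add_trivial:
            s.update(Split.trivial(i, n) for i in range(1, n + 1))
        for sp in s:
            if sp.n != n:
                raise ValueError(f"split {sp} is not a split of [{n}]")
        return SplitSystem(n, frozenset(s))

    @property
    def nontrivial(self) -> frozenset:
        return frozenset(s for s in self.splits if not s.is_trivial)

    def refines(self, other: "SplitSystem") -> bool:
        return other.splits <= self.splits

    def __len__(self) -> int:
        return len(self.splits)

    def __iter__(self) -> Iterator[Split]:
        return iter(self.splits)

    def __contains__(self, split: Split) -> bool:
        return split in self.splits


@dataclass(frozen=True)
class CircularOrder:
    """A cyclic order of [n], canonical up to rotation and reflection.

    The canonical representative starts at taxon 1 and proceeds toward the
    smaller of the two neighbours of 1.
    """

    seq: tuple

    @staticmethod
    def of(seq: Sequence[int]) -> "CircularOrder":
        seq = tuple(seq)
        n = len(seq)
        if sorted(seq) != list(range(1, n + 1)):
            raise ValueError("circular order must be a permutation of 1..n")
        if n <= 2:
            return CircularOrder(seq if seq[0] == 1 else tuple(reversed(seq)))
        k = seq.index(1)
        rot = seq[k:] + seq[:k]
        if rot[1] > rot[-1]:
            rot = (rot[0],) + tuple(reversed(rot[1:]))
        return CircularOrder(rot)

    @property
    def n(self) -> int:
        return len(self.seq)

    def adjacent_pairs(self) -> list:
        n = len(self.seq)
        return [tuple(sorted((self.seq[i], self.seq[(i + 1) % n]))) for i in range(n)]

    def is_contiguous(self, side: frozenset) -> bool:
        """True if ``side`` occupies a contiguous arc of this cyclic order."""
        n = len(self.seq)
        boundaries = 0
        for i in range(n):
            if (self.seq[i] in side) != (self.seq[(i + 1) % n] in side):
                boundaries += 1
                if boundaries > 2:
                    return False
        return boundaries == 2

    def __iter__(self) -> Iterator[int]:
        return iter(self.seq)


# ---------------------------------------------------------------------------
# the network type
# ---------------------------------------------------------------------------


class PhyloNetwork:
    """A validated, weighted, unrooted phylogenetic network.

    Parameters
    ----------
    graph:
        A simple connected :class:`networkx.Graph` with a ``weight`` attribute
        on every edge (missing weights default to 1).
    leaves:
        Mapping from taxon labels ``1..n`` to the degree-1 nodes of ``graph``.
    """

    def __init__(self, graph: nx.Graph, leaves: Mapping[int, Hashable], validate: bool = True):
        g = nx.Graph()
        for u, v, data in graph.edges(data=True):
            w = data.get("weight", 1)
            if isinstance(w, int):
                w = Fraction(w)
            g.add_edge(u, v, weight=w)
        g.add_nodes_from(graph.nodes)
        self.graph = g
        self.leaves = dict(sorted(leaves.items()))
        if validate:
            problems = validate_network(g, self.leaves)
            if problems:
                raise NetworkError(problems)

    # -- basic accessors ----------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.leaves)

    @property
    def leaf_nodes(self) -> set:
        return set(self.leaves.values())

    def label_of(self, node: Hashable) -> int:
        for lab, nd in self.leaves.items():
            if nd == node:
                return lab
        raise KeyError(node)

    def weight(self, u: Hashable, v: Hashable):
        return self.graph.edges[u, v]["weight"]

    @property
    def total_weight(self):
        return sum(d["weight"] for _, _, d in self.graph.edges(data=True))

    def has_positive_weights(self) -> bool:
        return all(d["weight"] > 0 for _, _, d in self.graph.edges(data=True))

    def copy(self) -> "PhyloNetwork":
        return PhyloNetwork(self.graph.copy(), self.leaves, validate=False)

    def unweighted(self) -> "PhyloNetwork":
        g = self.graph.copy()
        for u, v in g.edges():
            g.edges[u, v]["weight"] = Fraction(1)
        return PhyloNetwork(g, self.leaves, validate=False)

    @staticmethod
    def from_edges(
        edges: Iterable[tuple],
        leaves: Mapping[int, Hashable] | None = None,
        validate: bool = True,
    ) -> "PhyloNetwork":
        """Build from ``(u, v, weight)`` triples (weight optional).

        When ``leaves`` is omitted, every node that is an ``int`` and has
        degree 1 is taken to be the leaf with that label.
        """
        g = nx.Graph()
        for e in edges:
            if len(e) == 2:
                u, v = e
                w = Fraction(1)
            else:
                u, v, w = e
            g.add_edge(u, v, weight=w)
        if leaves is None:
            leaves = {u: u for u in g.nodes if isinstance(u, int) and g.degree(u) == 1}
        return PhyloNetwork(g, leaves, validate=validate)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloNetwork n={self.n} nodes={self.graph.number_of_nodes()} edges={self.graph.number_of_edges()}>"


def validate_network(graph: nx.Graph, leaves: Mapping[int, Hashable]) -> list:
    """Return a list of invariant violations (empty when valid)."""
    problems = []
    n = len(leaves)
    if sorted(leaves.keys()) != list(range(1, n + 1)):
        problems.append(f"leaf labels must be 1..{n}, got {sorted(leaves.keys())}")
    leaf_nodes = set(leaves.values())
    if len(leaf_nodes) != n:
        problems.append("leaf label map is not injective")
    if graph.number_of_nodes() == 0:
        problems.append("empty graph")
        return problems
    if not nx.is_connected(graph):
        problems.append("graph is not connected")
    for node in graph.nodes:
        d = graph.degree(node)
        if node in leaf_nodes:
            if d != 1:
                problems.append(f"labeled node {node!r} has degree {d}, expected 1")
        else:
            if d < 3:
                problems.append(f"unlabeled node {node!r} has degree {d} < 3")
    for u, v, data in graph.edges(data=True):
        w = data.get("weight", 1)
        if w < 0:
            problems.append(f"edge ({u!r},{v!r}) has negative weight {w}")
    for node in leaf_nodes:
        if node not in graph:
            problems.append(f"leaf node {node!r} missing from graph")
    return problems


# ---------------------------------------------------------------------------
# structure: bridges and blocks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Bridge:
    u: Hashable
    v: Hashable
    split: Split

    @property
    def is_trivial(self) -> bool:
        return self.split.is_trivial


@dataclass(frozen=True)
class Block:
    kind: str  # CYCLE, THETA or OTHER
    nodes: frozenset
    edges: frozenset  # frozenset of 2-element frozensets


def find_bridges(net: PhyloNetwork) -> list:
    """All cut edges, each with the split its deletion displays."""
    node_to_label = {v: k for k, v in net.leaves.items()}
    out = []
    for u, v in nx.bridges(net.graph):
        g = net.graph.copy()
        g.remove_edge(u, v)
        comp = nx.node_connected_component(g, u)
        side_a = {node_to_label[x] for x in comp if x in node_to_label}
        side_b = set(net.leaves) - side_a
        out.append(Bridge(u, v, Split.of(side_a, side_b)))
    return out


def cycle_blocks(net: PhyloNetwork) -> list:
    """Biconnected blocks with more than one edge, classified by shape.

    CYCLE blocks are simple cycles; THETA blocks are two degree-3 nodes
    joined by three internally disjoint paths (a chorded cycle); anything
    else is OTHER.
    """
    blocks = []
    for comp in nx.biconnected_components(net.graph):
        if len(comp) <= 2:
            continue
        sub = net.graph.subgraph(comp)
        degs = sorted(dict(sub.degree()).values())
        if all(d == 2 for d in degs):
            kind = CYCLE
        elif degs.count(3) == 2 and degs.count(2) == len(degs) - 2:
            kind = THETA
        else:
            kind = OTHER
        blocks.append(
            Block(
                kind,
                frozenset(comp),
                frozenset(frozenset(e) for e in sub.edges()),
            )
        )
    return blocks


@dataclass(frozen=True)
class Nestedness:
    level: int  # 0, 1, 2, or 3 meaning "more than 2"
    triangle_free: bool


def nestedness_level(net: PhyloNetwork) -> Nestedness:
    """Nestedness of the network: 0 = tree, 1 = cycles only, 2 = cycles and
    thetas with at least one theta, 3 = some edge in more than two cycles."""
    blocks = cycle_blocks(net)
    tri_free = True
    for b in blocks:
        sub = net.graph.subgraph(b.nodes)
        if any(t > 0 for t in nx.triangles(sub).values()):
            tri_free = False
    if not blocks:
        return Nestedness(0, tri_free)
    kinds = {b.kind for b in blocks}
    if kinds == {CYCLE}:
        return Nestedness(1, tri_free)
    if kinds <= {CYCLE, THETA}:
        return Nestedness(2, tri_free)
    return Nestedness(3, tri_free)


def is_binary(net: PhyloNetwork) -> bool:
    """True if every unlabeled node has degree exactly 3."""
    leaf_nodes = net.leaf_nodes
    return all(
        net.graph.degree(v) == 3 for v in net.graph.nodes if v not in leaf_nodes
    )


# ---------------------------------------------------------------------------
# displayed splits and consistent circular orders
# ---------------------------------------------------------------------------


def sigma_splits(net: PhyloNetwork) -> SplitSystem:
    """The split system Sigma(N) displayed by a 1-nested network.

    Bridges display their split; each unordered pair of edges of a cycle
    block is a minimal cut displaying a split.  Duplicate bipartitions are
    merged.
    """
    nest = nestedness_level(net)
    if nest.level > 1:
        raise NetworkError([f"Sigma is defined for 1-nested networks; level is {nest.level}"])
    node_to_label = {v: k for k, v in net.leaves.items()}
    splits = set()
    for br in find_bridges(net):
        splits.add(br.split)
    for block in cycle_blocks(net):
        edges = [tuple(e) for e in block.edges]
        for (u1, v1), (u2, v2) in itertools.combinations(edges, 2):
            g = net.graph.copy()
            g.remove_edge(u1, v1)
            g.remove_edge(u2, v2)
            comp = nx.node_connected_component(g, u1)
            side_a = {node_to_label[x] for x in comp if x in node_to_label}
            side_b = set(net.leaves) - side_a
            splits.add(Split.of(side_a, side_b))
    return SplitSystem.of(net.n, splits, add_trivial=True)


def split_equivalent(a: PhyloNetwork, b: PhyloNetwork) -> bool:
    """True if the two 1-nested networks display the same splits."""
    if set(a.leaves) != set(b.leaves):
        raise ValueError("networks have different leaf sets")
    return sigma_splits(a) == sigma_splits(b)


def canonical_order_candidates(n: int) -> Iterator[CircularOrder]:
    """All canonical circular orders of [n]: taxon 1 first, second neighbour
    smaller than the last.  There are (n-1)!/2 of them for n >= 3."""
    if n <= 2:
        yield CircularOrder(tuple(range(1, n + 1)))
        return
    rest = list(range(2, n + 1))
    for perm in itertools.permutations(rest):
        if perm[0] < perm[-1]:
            yield CircularOrder((1,) + perm)


def orders_of_system(system: SplitSystem, bound: int = 9) -> set:
    """All canonical circular orders in which every split of the system has
    both parts contiguous.  Brute force over the (n-1)!/2 canonical orders."""
    n = system.n
    if n > bound:
        raise ValueError(f"order search bound exceeded: n={n} > {bound}")
    nontrivial = [s.part_a for s in system.nontrivial]
    found = set()
    for order in canonical_order_candidates(n):
        if all(order.is_contiguous(side) for side in nontrivial):
            found.add(order)
    return found


def consistent_orders(net: PhyloNetwork, bound: int = 9) -> set:
    """Circular leaf orders consistent with a 1-nested network (the orders in
    which every displayed split is contiguous)."""
    return orders_of_system(sigma_splits(net), bound=bound)
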