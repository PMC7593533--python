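"""Maps between weighted 1-nested networks and weighted circular split systems.

Four maps are implemented:

* ``rw_direct`` -- weight every displayed split of a 1-nested network by the
  sum of its displays: a bridge display contributes the bridge weight w(e); a
  cycle-pair display with cut-edge weights a, x in a cycle of total weight z
  contributes a*x/z.  The split metric of the result equals the resistance
  distance of the network exactly.
* ``rw_metric`` -- the same system obtained the long way round: compute the
  resistance leaf vector, then circular-decompose it along a consistent order.
* ``sw`` -- the analogue for the minimum path distance.
* ``L_exterior`` / ``lw`` -- the (weighted) exterior map taking a circular
  split system back to a 1-nested phylogenetic network.  The reconstruction
  is purely combinatorial: non-trivial splits are read as arcs of a circular
  order, arcs that pairwise cross are merged into crossing classes, each
  class of size >= 2 becomes a cycle whose nodes are the sectors cut out by
  the class's arc boundaries, singleton classes become bridges, and trivial
  splits become leaf edges.  Edge weights sum the weights of the splits whose
  exterior representative smooths into that edge: a bridge or leaf edge takes
  its own split's weight; a cycle edge takes the weights of the class splits
  with an arc boundary at that position.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .distance import DistanceVector, min_path_vector, resistance_leaf_vector, find_kalmanson_order
from .network import (
    CYCLE,
    CircularOrder,
    NetworkError,
    PhyloNetwork,
    Split,
    SplitSystem,
    consistent_orders,
    cycle_blocks,
    find_bridges,
    nestedness_level,
    sigma_splits,
)
from .splits import NotKalmansonError, WeightedSplitSystem, circular_decompose, split_metric

__all__ = [
    "rw_direct",
    "rw_metric",
    "sw",
    "L_exterior",
    "lw",
    "marguerite",
    "MargueriteCounts",
]


# ---------------------------------------------------------------------------
# network -> weighted split system
# ---------------------------------------------------------------------------


def rw_direct(net: PhyloNetwork) -> WeightedSplitSystem:
    """Weighted split system of a positive-weighted 1-nested network, built
    directly from its displays, bypassing both the metric computation and any
    agglomerative algorithm."""
    if nestedness_level(net).level > 1:
        raise NetworkError(["rw_direct requires a 1-nested network"])
    node_to_label = {v: k for k, v in net.leaves.items()}
    weights: dict = {}

    def add(split: Split, w) -> None:
        weights[split] = weights.get(split, 0) + w

    for br in find_bridges(net):
        add(br.split, net.weight(br.u, br.v))
    for block in cycle_blocks(net):
        edges = [tuple(e) for e in block.edges]
        z = sum(net.weight(u, v) for u, v in edges)
        for (u1, v1), (u2, v2) in itertools.combinations(edges, 2):
            g = net.graph.copy()
            g.remove_edge(u1, v1)
            g.remove_edge(u2, v2)
            comp = nx.node_connected_component(g, u1)
            side_a = {node_to_label[x] for x in comp if x in node_to_label}
            split = Split.of(side_a, set(net.leaves) - side_a)
            add(split, net.weight(u1, v1) * net.weight(u2, v2) / z)
    return WeightedSplitSystem.of(net.n, weights)


def rw_metric(net: PhyloNetwork, mode: str = "exact") -> WeightedSplitSystem:
    """The unique weighted circular split system whose split metric is the
    resistance distance of the network, obtained by circular decomposition
    along a consistent order.  Equals :func:`rw_direct`."""
    d = resistance_leaf_vector(net, mode=mode)
    order = min(consistent_orders(net), key=lambda o: o.seq)
    tol = 0 if mode == "exact" else 1e-9
    return circular_decompose(d, order, tol=tol)


def sw(net: PhyloNetwork, tol=0) -> WeightedSplitSystem:
    """The unique weighted circular split system with the same minimum path
    distance vector as the network.

    Works for any network whose minimum path metric is Kalmanson for some
    circular order (1-nested always; 2-nested networks are accepted when an
    order exists)."""
    d = min_path_vector(net)
    order = None
    if nestedness_level(net).level <= 1:
        order = min(consistent_orders(net), key=lambda o: o.seq)
    else:
        order = find_kalmanson_order(d, tol=tol)
    if order is None:
        raise NotKalmansonError(
            "minimum path metric is not Kalmanson for any circular order"
        )
    return circular_decompose(d, order, tol=tol)


# ---------------------------------------------------------------------------
# split system -> network (the exterior map)
# ---------------------------------------------------------------------------


def _arc_interval(split: Split, pos: Mapping[int, int], anchor: int):
    """The side of the split avoiding the anchor taxon (the one at position
    0), as a position interval (a, b) with 1 <= a <= b <= n-1; None when the
    side is not contiguous in the order."""
    side = split.side_without(anchor)
    ps = sorted(pos[t] for t in side)
    if ps[-1] - ps[0] + 1 != len(ps):
        return None
    return (ps[0], ps[-1])


def _crosses(a, b) -> bool:
    (a1, b1), (a2, b2) = a, b
    return (a1 < a2 <= b1 < b2) or (a2 < a1 <= b2 < b1)


class _Item:
    """A bridge or a cycle in the exterior reconstruction."""

    __slots__ = ("kind", "interval", "splits", "children")

    def __init__(self, kind, interval, splits):
        self.kind = kind  # "bridge" | "cycle"
        self.interval = interval  # (a, b) position interval of the union
        self.splits = splits  # bridge: [split]; cycle: list of (interval, split)
        self.children = []


def _build_exterior(
    n: int,
    nontrivial: Iterable[Split],
    order: CircularOrder,
    weight_of=None,
):
    """Construct the smoothed exterior network for a circular split system.

    Returns (graph, leaves) with each edge carrying ``weight`` (summed from
    the splits attributed to it; 1 per split when ``weight_of`` is None for
    the unweighted map)."""
    seq = tuple(order)
    pos = {t: i for i, t in enumerate(seq)}
    get_w = weight_of if weight_of is not None else (lambda sp: Fraction(1))

    arcs = []
    for sp in set(nontrivial):
        iv = _arc_interval(sp, pos, seq[0])
        if iv is None:
            raise ValueError(f"split {sp} is not contiguous in order {seq}")
        arcs.append((iv, sp))

    # crossing classes: connected components of the pairwise-crossing relation
    parent = list(range(len(arcs)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in itertools.combinations(range(len(arcs)), 2):
        if _crosses(arcs[i][0], arcs[j][0]):
            parent[find(i)] = find(j)
    classes: dict = {}
    for i in range(len(arcs)):
        classes.setdefault(find(i), []).append(arcs[i])

    items = []
    for members in classes.values():
        if len(members) == 1:
            iv, sp = members[0]
            items.append(_Item("bridge", iv, [sp]))
        else:
            lo = min(iv[0] for iv, _ in members)
            hi = max(iv[1] for iv, _ in members)
            items.append(_Item("cycle", (lo, hi), members))

    # inclusion forest; on equal intervals a bridge wraps a cycle
    def contains(p: _Item, c: _Item) -> bool:
        (a1, b1), (a2, b2) = p.interval, c.interval
        if (a1, b1) == (a2, b2):
            return p.kind == "bridge" and c.kind == "cycle"
        return a1 <= a2 and b2 <= b1

    roots = []
    for it in items:
        containers = [o for o in items if o is not it and contains(o, it)]
        if not containers:
            roots.append(it)
        else:
            # smallest container; a cycle beats the bridge wrapping it
            par = min(
                containers,
                key=lambda o: (o.interval[1] - o.interval[0], o.kind == "bridge"),
            )
            par.children.append(it)

    g = nx.Graph()
    leaves = {}
    counter = itertools.count()

    def new_node():
        return f"v{next(counter)}"

    def add_edge(u, v, splits_here):
        w = sum((get_w(sp) for sp in splits_here), Fraction(0))
        g.add_edge(u, v, weight=w, splits=frozenset(splits_here))

    def add_leaf(node, position):
        taxon = seq[position]
        leaf = f"leaf{taxon}"
        leaves[taxon] = leaf
        triv = Split.trivial(taxon, n)
        add_edge(node, leaf, [triv])

    def populate(node, lo, hi, children):
        """Attach child items and uncovered leaf positions of [lo, hi]."""
        covered = set()
        for ch in children:
            attach(node, ch)
            covered.update(range(ch.interval[0], ch.interval[1] + 1))
        for p in range(lo, hi + 1):
            if p not in covered:
                add_leaf(node, p)

    def attach(parent_node, item: _Item):
        if item.kind == "bridge":
            below = new_node()
            add_edge(parent_node, below, item.splits)
            populate(below, item.interval[0], item.interval[1], item.children)
            return
        # cycle: sectors between the arc-boundary cuts
        cuts = set()
        for (a, b), _ in item.splits:
            cuts.add(a - 1)  # gap between positions a-1 and a
            cuts.add(b)  # gap between positions b and b+1
        cuts = sorted(cuts)
        m = len(cuts)
        # sector t holds circular positions cuts[t]+1 .. cuts[t+1]
        sectors = []
        for t in range(m):
            start = (cuts[t] + 1) % n
            end = cuts[(t + 1) % m]
            positions = []
            p = start
            while True:
                positions.append(p)
                if p == end:
                    break
                p = (p + 1) % n
            sectors.append(positions)
        sector_nodes = []
        outside_idx = None
        for t, positions in enumerate(sectors):
            if 0 in positions:
                sector_nodes.append(parent_node)
                outside_idx = t
            else:
                sector_nodes.append(new_node())
        if outside_idx is None:
            raise ValueError("cycle class covers the whole circle")
        # cycle edges; the edge after sector t sits at cut[(t+1) % m]
        for t in range(m):
            cut_here = cuts[(t + 1) % m]
            at_cut = [
                sp
                for (a, b), sp in item.splits
                if a - 1 == cut_here or b == cut_here
            ]
            add_edge(sector_nodes[t], sector_nodes[(t + 1) % m], at_cut)
        # distribute children into sectors and fill leaves
        for t, positions in enumerate(sectors):
            if t == outside_idx:
                continue
            kids = [
                ch
                for ch in item.children
                if ch.interval[0] in positions
            ]
            node = sector_nodes[t]
            covered = set()
            for ch in kids:
                attach(node, ch)
                covered.update(range(ch.interval[0], ch.interval[1] + 1))
            for p in positions:
                if p not in covered:
                    add_leaf(node, p)

    root = new_node()
    g.add_node(root)
    add_leaf(root, 0)
    populate(root, 1, n - 1, roots)

    # smooth any unlabeled degree-2 node, merging weights and split tags
    leaf_nodes = set(leaves.values())
    changed = True
    while changed:
        changed = False
        for v in list(g.nodes):
            if v in leaf_nodes or g.degree(v) != 2:
                continue
            (u, w) = list(g.neighbors(v))
            if g.has_edge(u, w):
                continue  # smoothing would create a multi-edge; keep the node
            wt = g.edges[u, v]["weight"] + g.edges[v, w]["weight"]
            tags = g.edges[u, v]["splits"] | g.edges[v, w]["splits"]
            g.remove_node(v)
            g.add_edge(u, w, weight=wt, splits=tags)
            changed = True
    return g, leaves


def _system_order(system, bound: int = 9) -> CircularOrder:
    orders = system.orders(bound=bound) if hasattr(system, "orders") else None
    if orders is None:
        from .network import orders_of_system

        orders = orders_of_system(system, bound=bound)
    if not orders:
        raise ValueError("split system is not circular: no consistent order exists")
    return min(orders, key=lambda o: o.seq)


def L_exterior(system: SplitSystem, order: CircularOrder | None = None) -> PhyloNetwork:
    """The smoothed exterior 1-nested network of a circular split system
    (unweighted: all edges get weight 1)."""
    if isinstance(system, WeightedSplitSystem):
        system = system.base_with_trivial()
    if order is None:
        order = _system_order(system)
    g, leaves = _build_exterior(system.n, system.nontrivial, order, weight_of=None)
    for u, v in g.edges:
        g.edges[u, v]["weight"] = Fraction(1)
    return PhyloNetwork(g, leaves)


def lw(system: WeightedSplitSystem, order: CircularOrder | None = None) -> PhyloNetwork:
    """The weighted exterior network: same graph as ``L_exterior`` of the
    unweighted system, with each edge weighted by the sum of the weights of
    the splits attributed to it."""
    if order is None:
        order = _system_order(system)
    nontrivial = [sp for sp in system.splits if not sp.is_trivial]
    g, leaves = _build_exterior(
        system.n, nontrivial, order, weight_of=lambda sp: system.weight(sp)
    )
    return PhyloNetwork(g, leaves)


# ---------------------------------------------------------------------------
# marguerite counts and graph
# ---------------------------------------------------------------------------


class MargueriteCounts(tuple):
    """(parallelograms, interior_sides, exterior_sides) of an m-marguerite."""

    def __new__(cls, m: int):
        if m < 5:
            raise ValueError("marguerite requires cycle length m >= 5")
        return super().__new__(cls, (m * m - 4 * m, m * (m - 5), m * (m - 3)))

    @property
    def parallelograms(self):
        return self[0]

    @property
    def interior_sides(self):
        return self[1]

    @property
    def exterior_sides(self):
        return self[2]


def marguerite(m: int, graph: bool = False):
    """Counts (and optionally the graph) of the m-marguerite: the ring of
    m^2 - 4m parallelograms representing an m-cycle as a split network.

    In graph mode, returns ``(counts, G, attachment_nodes)`` where the
    attachment nodes are the m degree-2 outer rhombus corners to which the
    pendant bridges are attached.
    """
    counts = MargueriteCounts(m)
    if not graph:
        return counts
    t = m - 5
    g = nx.Graph()
    outer = [f"o{i}" for i in range(m)]
    left = [f"p{i}" for i in range(m)]  # rhombus i's left corner
    right = [f"r{i}" for i in range(m)]  # rhombus i's right corner
    inner = [f"q{i}" for i in range(m)]
    if t == 0:
        # strips are empty: rhombi share side edges and all inner corners meet
        for i in range(m):
            right[i] = left[(i + 1) % m]
            inner[i] = "center"
    for i in range(m):
        g.add_edge(outer[i], left[i])
        g.add_edge(outer[i], right[i])
        g.add_edge(left[i], inner[i])
        g.add_edge(right[i], inner[i])
    if t > 0:
        for i in range(m):
            nxt = (i + 1) % m
            top = [right[i]] + [f"t{i}_{k}" for k in range(1, t)] + [left[nxt]]
            bot = [inner[i]] + [f"b{i}_{k}" for k in range(1, t)] + [inner[nxt]]
            for k in range(t):
                g.add_edge(top[k], top[k + 1])
                g.add_edge(bot[k], bot[k + 1])
            for k in range(t + 1):
                g.add_edge(top[k], bot[k])
    attachment = [v for v in outer if g.degree(v) == 2]
    return counts, g, attachment
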