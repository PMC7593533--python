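"""File formats: the JSON network dialect, GraphML, PHYLIP distance
matrices, and NEXUS DISTANCES / SPLITS blocks (SplitsTree dialect).

The JSON dialect is the repository's canonical lossless form::

    {"n": 4,
     "leaves": {"1": "leaf1", ...},
     "edges": [["u", "v", "3/2"], ...]}

Rational weights are serialized as "p/q" strings so exact round trips are
lossless; plain numbers are accepted and read as floats.
"""

from __future__ import annotations

import json
import re
from fractions import Fraction
from typing import IO, Iterable, Mapping, Sequence

import networkx as nx

from .distance import DistanceVector, lex_pairs
from .network import CircularOrder, PhyloNetwork, Split
from .splits import WeightedSplitSystem

__all__ = [
    "network_to_json",
    "network_from_json",
    "read_network",
    "write_network",
    "read_network_graphml",
    "write_network_graphml",
    "read_phylip",
    "write_phylip",
    "read_nexus_distances",
    "write_nexus_distances",
    "read_splits_nexus",
    "write_splits_nexus",
    "format_weight",
    "parse_weight",
]


def format_weight(w) -> str:
    if isinstance(w, Fraction):
        return f"{w.numerator}/{w.denominator}" if w.denominator != 1 else str(w.numerator)
    return repr(w)


def parse_weight(s):
    if isinstance(s, (int, float)):
        return Fraction(s) if isinstance(s, int) else s
    s = str(s)
    if "/" in s:
        num, den = s.split("/")
        return Fraction(int(num), int(den))
    try:
        return Fraction(int(s))
    except ValueError:
        return float(s)


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------


def network_to_json(net: PhyloNetwork) -> dict:
    return {
        "n": net.n,
        "leaves": {str(k): str(v) for k, v in net.leaves.items()},
        "edges": [
            [str(u), str(v), format_weight(d["weight"])]
            for u, v, d in sorted(net.graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1])))
        ],
    }


def network_from_json(obj: Mapping) -> PhyloNetwork:
    for key in ("n", "leaves", "edges"):
        if key not in obj:
            raise ValueError(f"network JSON missing field {key!r}")
    g = nx.Graph()
    for entry in obj["edges"]:
        if len(entry) == 2:
            u, v = entry
            w = Fraction(1)
        elif len(entry) == 3:
            u, v, w = entry
            w = parse_weight(w)
        else:
            raise ValueError(f"bad edge entry {entry!r}")
        g.add_edge(str(u), str(v), weight=w)
    leaves = {int(k): str(v) for k, v in obj["leaves"].items()}
    if len(leaves) != int(obj["n"]):
        raise ValueError("field 'n' disagrees with the leaf map")
    return PhyloNetwork(g, leaves)


def write_network(net: PhyloNetwork, path) -> None:
    with open(path, "w") as fh:
        json.dump(network_to_json(net), fh, indent=1)
        fh.write("\n")


def read_network(path) -> PhyloNetwork:
    with open(path) as fh:
        return network_from_json(json.load(fh))


def write_network_graphml(net: PhyloNetwork, path) -> None:
    g = nx.Graph()
    node_to_label = {v: k for k, v in net.leaves.items()}
    for u, v, d in net.graph.edges(data=True):
        g.add_edge(str(u), str(v), w=format_weight(d["weight"]))
    for node, label in node_to_label.items():
        g.nodes[str(node)]["taxon"] = int(label)
    nx.write_graphml(g, path)


def read_network_graphml(path) -> PhyloNetwork:
    g0 = nx.read_graphml(path)
    g = nx.Graph()
    for u, v, d in g0.edges(data=True):
        g.add_edge(u, v, weight=parse_weight(d.get("w", 1)))
    leaves = {
        int(d["taxon"]): v for v, d in g0.nodes(data=True) if "taxon" in d
    }
    return PhyloNetwork(g, leaves)


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------


def write_phylip(d: DistanceVector, path, names: Sequence[str] | None = None) -> None:
    """PHYLIP square distance matrix (relaxed names)."""
    n = d.n
    names = list(names) if names else [f"t{i}" for i in range(1, n + 1)]
    with open(path, "w") as fh:
        fh.write(f"{n}\n")
        for i in range(1, n + 1):
            row = " ".join(format(float(d.get(i, j)), ".12g") for j in range(1, n + 1))
            fh.write(f"{names[i-1]} {row}\n")


def read_phylip(path) -> DistanceVector:
    with open(path) as fh:
        tokens = fh.read().split()
    n = int(tokens[0])
    pos = 1
    rows = []
    for _ in range(n):
        pos += 1  # skip the name
        rows.append([float(x) for x in tokens[pos : pos + n]])
        pos += n
    return DistanceVector.from_function(n, lambda i, j: rows[i - 1][j - 1])


def write_nexus_distances(d: DistanceVector, path, names: Sequence[str] | None = None) -> None:
    n = d.n
    names = list(names) if names else [f"t{i}" for i in range(1, n + 1)]
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN TAXA;\n")
        fh.write(f"DIMENSIONS NTAX={n};\nTAXLABELS {' '.join(names)};\nEND;\n\n")
        fh.write("BEGIN DISTANCES;\nFORMAT TRIANGLE=BOTH;\nMATRIX\n")
        for i in range(1, n + 1):
            row = " ".join(format(float(d.get(i, j)), ".12g") for j in range(1, n + 1))
            fh.write(f"{names[i-1]} {row}\n")
        fh.write(";\nEND;\n")


def read_nexus_distances(path) -> DistanceVector:
    with open(path) as fh:
        text = fh.read()
    m = re.search(r"BEGIN DISTANCES;.*?MATRIX\s*(.*?);", text, re.S | re.I)
    if not m:
        raise ValueError("no DISTANCES block found")
    lines = [ln.split() for ln in m.group(1).strip().splitlines() if ln.strip()]
    n = len(lines)
    rows = [[float(x) for x in ln[1:]] for ln in lines]
    return DistanceVector.from_function(n, lambda i, j: rows[i - 1][j - 1])


# ---------------------------------------------------------------------------
# NEXUS SPLITS (SplitsTree dialect)
# ---------------------------------------------------------------------------


def write_splits_nexus(system: WeightedSplitSystem, path, order: CircularOrder | None = None) -> None:
    """TAXA + SPLITS blocks with a CYCLE statement, readable by SplitsTree.

    Split lines list the side containing taxon 1, weights at full precision.
    """
    n = system.n
    if order is None:
        orders = system.orders()
        if not orders:
            raise ValueError("system is not circular; no CYCLE order to write")
        order = min(orders, key=lambda o: o.seq)
    splits = sorted(
        system.weights.items(), key=lambda kv: (len(kv[0].part_a), sorted(kv[0].part_a))
    )
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN TAXA;\n")
        fh.write(f"DIMENSIONS NTAX={n};\n")
        fh.write("TAXLABELS " + " ".join(f"t{i}" for i in range(1, n + 1)) + ";\nEND;\n\n")
        fh.write("BEGIN SPLITS;\n")
        fh.write(f"DIMENSIONS NTAX={n} NSPLITS={len(splits)};\n")
        fh.write("FORMAT LABELS=NO WEIGHTS=YES;\n")
        fh.write("CYCLE " + " ".join(str(t) for t in order) + ";\n")
        fh.write("MATRIX\n")
        for sp, w in splits:
            side = sp.part_a if 1 in sp.part_a else sp.part_b
            fh.write(f"[{format_weight(w)}] {float(w):.12g} " + " ".join(map(str, sorted(side))) + ",\n")
        fh.write(";\nEND;\n")


def read_splits_nexus(path) -> WeightedSplitSystem:
    with open(path) as fh:
        text = fh.read()
    mt = re.search(r"BEGIN TAXA;.*?NTAX\s*=\s*(\d+)", text, re.S | re.I)
    if not mt:
        raise ValueError("no TAXA block found")
    n = int(mt.group(1))
    ms = re.search(r"BEGIN SPLITS;.*?MATRIX\s*(.*?);", text, re.S | re.I)
    if not ms:
        raise ValueError("no SPLITS block found")
    weights = {}
    for line in ms.group(1).strip().splitlines():
        line = line.strip().rstrip(",")
        if not line:
            continue
        exact = re.match(r"\[([^\]]+)\]\s*(.*)", line)
        if exact:
            w = parse_weight(exact.group(1))
            rest = exact.group(2).split()
            members = [int(x) for x in rest[1:]]
        else:
            parts = line.split()
            w = float(parts[0])
            members = [int(x) for x in parts[1:]]
        side = frozenset(members)
        weights[Split.of(side, set(range(1, n + 1)) - side)] = w
    return WeightedSplitSystem.of(n, weights)
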