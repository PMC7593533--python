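"""Leaf-label-respecting isomorphism utilities for network enumeration."""

from __future__ import annotations

import networkx as nx

from .network import PhyloNetwork

__all__ = ["labelled_graph", "certificate", "isomorphic", "dedupe"]


def labelled_graph(net: PhyloNetwork) -> nx.Graph:
    """Copy of the graph with a ``label`` node attribute: the taxon as a
    string on leaves, empty on internal nodes."""
    g = nx.Graph()
    node_to_label = {v: str(k) for k, v in net.leaves.items()}
    for u, v in net.graph.edges():
        g.add_edge(u, v)
    for v in g.nodes:
        g.nodes[v]["label"] = node_to_label.get(v, "")
    return g


def certificate(net: PhyloNetwork) -> str:
    """Isomorphism-invariant hash respecting leaf labels (Weisfeiler-Lehman).

    Equal certificates are verified with exact isomorphism in :func:`dedupe`;
    distinct certificates are guaranteed non-isomorphic.
    """
    return nx.weisfeiler_lehman_graph_hash(labelled_graph(net), node_attr="label", iterations=4)


def isomorphic(a: PhyloNetwork, b: PhyloNetwork) -> bool:
    """Graph isomorphism that fixes the leaf labels."""
    return nx.is_isomorphic(
        labelled_graph(a),
        labelled_graph(b),
        node_match=lambda x, y: x["label"] == y["label"],
    )


def dedupe(nets: list) -> list:
    """Remove leaf-label-preserving isomorphism duplicates."""
    buckets: dict = {}
    out = []
    for net in nets:
        key = certificate(net)
        group = buckets.setdefault(key, [])
        if not any(isomorphic(net, other) for other in group):
            group.append(net)
            out.append(net)
    return out
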