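"""Topological-overlap (TOM) edge weighting.

An unweighted interaction network carries no notion of how much signal an
edge can transmit. The topological overlap measure scores an edge by how
much the two endpoints' neighbourhoods overlap:

    TOM(x, y) = (|N(x) ∩ N(y)| + A_xy) / (min(|N(x)|, |N(y)|) + 1 - A_xy)

where N(v) is the neighbour set of v (excluding v itself) and A_xy is the
0/1 adjacency indicator. For an existing edge the value lies in [0, 1] and
is used downstream as the flow capacity of that edge.
"""

from __future__ import annotations

import networkx as nx

#: Edge attribute under which the TOM weight / flow capacity is stored.
TOM_ATTR = "tom"


def tom_similarity(net: nx.Graph, x: str, y: str) -> float:
    """Topological overlap between two distinct nodes of an undirected graph.

    The neighbour sets exclude the nodes themselves (the graph has no
    self-loops, and x ∈ N(y) / y ∈ N(x) never enter the intersection).
    For two adjacent nodes the denominator is at least 1, since each
    endpoint has at least the other as a neighbour.
    """
    if x == y:
        raise ValueError(f"TOM similarity is undefined for a node with itself ({x!r})")
    if x not in net:
        raise KeyError(f"unknown node {x!r}")
    if y not in net:
        raise KeyError(f"unknown node {y!r}")
    nbr_x = set(net[x])
    nbr_y = set(net[y])
    a_xy = 1 if net.has_edge(x, y) else 0
    shared = len(nbr_x & nbr_y)
    denom = min(len(nbr_x), len(nbr_y)) + 1 - a_xy
    if denom <= 0:
        # only possible for non-adjacent isolated pairs, where min(...)=0 and
        # denom=1; guard kept as a hard invariant.
        raise AssertionError("TOM denominator must be >= 1")
    return (shared + a_xy) / denom


def weight_network(net: nx.Graph) -> nx.Graph:
    """Assign every edge its TOM weight (flow capacity) under ``TOM_ATTR``.

    Returns a copy of the graph; weights lie in [0, 1]. Edges whose TOM is 0
    are retained with capacity 0 so the topology stays intact for rankers
    that ignore weights.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("cannot weight an empty network")
    wnet = net.copy()
    for u, v in wnet.edges():
        w = tom_similarity(net, u, v)
        assert 0.0 <= w <= 1.0
        wnet[u][v][TOM_ATTR] = w
    return wnet


def write_weighted_edges(wnet: nx.Graph, path) -> None:
    """Write the weighted network as TSV (node1, node2, tom_weight) at 8 s.f."""
    rows = sorted((min(u, v), max(u, v), d[TOM_ATTR]) for u, v, d in wnet.edges(data=True))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# node1\tnode2\ttom_weight\n")
        for u, v, w in rows:
            fh.write(f"{u}\t{v}\t{w:.8g}\n")


def read_weighted_edges(path) -> nx.Graph:
    """Read a (node1, node2, weight) TSV back into a TOM-weighted graph."""
    from .io import NetworkFormatError, _data_lines

    wnet = nx.Graph()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise NetworkFormatError(f"{path}:{lineno}: expected 3 tab-separated fields, got {line!r}")
        u, v, w = fields[0], fields[1], float(fields[2])
        if u == v:
            continue
        wnet.add_edge(u, v, **{TOM_ATTR: w})
    if wnet.number_of_edges() == 0:
        raise NetworkFormatError(f"{path}: no weighted edges found")
    return wnet
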