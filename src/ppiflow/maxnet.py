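"""Construction of the single-source / single-sink flow network ("MaxNet").

The drug-repurposing question — how much interaction signal can travel from
the set of druggable proteins to the set of disease risk genes — is posed as
one maximum-flow problem by adding two dummy terminals:

* a source ``__SDN__`` with an arc to every mapped drug target, and
* a sink ``__DDN__`` with an arc from every mapped risk gene.

Each undirected TOM-weighted edge becomes two antiparallel directed arcs of
equal capacity (flow may traverse a physical interaction in either
direction). The dummy arc into a target t carries capacity equal to the sum
of t's real outgoing capacities, and the dummy arc out of a risk gene g the
sum of g's real incoming capacities, so the dummy arcs never bind more
tightly than the node's own edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .io import NodeSet
from .tom import TOM_ATTR

SOURCE = "__SDN__"
SINK = "__DDN__"

#: What to do with a node that is both a drug target and a risk gene.
OVERLAP_POLICIES = ("both", "target_only", "gene_only")


@dataclass
class FlowNetwork:
    """A directed flow network with designated source and sink.

    Invariants: the source has no incoming arcs, the sink no outgoing arcs,
    all capacities are >= 0, and every real (non-dummy) arc has an
    antiparallel twin of equal capacity.
    """

    nodes: set[str]
    arcs: dict[tuple[str, str], float]
    source: str = SOURCE
    sink: str = SINK

    def out_arcs(self, u: str) -> list[tuple[str, float]]:
        return [(v, c) for (a, v), c in self.arcs.items() if a == u]

    @property
    def n_arcs(self) -> int:
        return len(self.arcs)


@dataclass(frozen=True)
class MaxNetSummary:
    n_nodes: int
    n_arcs: int
    n_source_arcs: int
    n_sink_arcs: int
    total_source_capacity: float
    total_sink_capacity: float


def build_maxnet(
    wnet: nx.Graph,
    targets: NodeSet,
    risk_genes: NodeSet,
    overlap_policy: str = "both",
) -> FlowNetwork:
    """Build the flow network from a TOM-weighted graph and two node sets.

    ``targets`` and ``risk_genes`` must already be mapped onto ``wnet``
    (every ID present in the graph). ``overlap_policy`` decides whether a
    node in both sets receives a source arc, a sink arc, or both (default).
    """
    if overlap_policy not in OVERLAP_POLICIES:
        raise ValueError(f"overlap_policy must be one of {OVERLAP_POLICIES}")
    if not targets.ids or not risk_genes.ids:
        raise ValueError("target and risk-gene sets must be non-empty")
    for reserved in (SOURCE, SINK):
        if reserved in wnet:
            raise ValueError(f"reserved node ID {reserved!r} already present in the network")
    missing = [t for t in targets.ids if t not in wnet] + [g for g in risk_genes.ids if g not in wnet]
    if missing:
        raise ValueError(f"node set not mapped onto network; unknown IDs e.g. {sorted(missing)[:5]}")

    arcs: dict[tuple[str, str], float] = {}
    for u, v, data in wnet.edges(data=True):
        cap = float(data[TOM_ATTR])
        if cap < 0:
            raise ValueError(f"negative capacity on edge {u!r}-{v!r}")
        arcs[(u, v)] = cap
        arcs[(v, u)] = cap

    overlap = targets.ids & risk_genes.ids

    def incident_capacity(node: str) -> float:
        return sum(float(d[TOM_ATTR]) for _, _, d in wnet.edges(node, data=True))

    for t in sorted(targets.ids):
        if t in overlap and overlap_policy == "gene_only":
            continue
        arcs[(SOURCE, t)] = incident_capacity(t)
    for g in sorted(risk_genes.ids):
        if g in overlap and overlap_policy == "target_only":
            continue
        arcs[(g, SINK)] = incident_capacity(g)

    nodes = set(wnet.nodes()) | {SOURCE, SINK}
    return FlowNetwork(nodes=nodes, arcs=arcs)


def maxnet_summary(fn: FlowNetwork) -> MaxNetSummary:
    """Node/arc counts and terminal-side capacities of a flow network."""
    src = [(a, c) for a, c in fn.arcs.items() if a[0] == fn.source]
    snk = [(a, c) for a, c in fn.arcs.items() if a[1] == fn.sink]
    return MaxNetSummary(
        n_nodes=len(fn.nodes),
        n_arcs=len(fn.arcs),
        n_source_arcs=len(src),
        n_sink_arcs=len(snk),
        total_source_capacity=sum(c for _, c in src),
        total_sink_capacity=sum(c for _, c in snk),
    )


def strip_terminals(fn: FlowNetwork) -> nx.Graph:
    """Recover the undirected weighted base graph by removing the dummy terminals."""
    base = nx.Graph()
    for (u, v), c in fn.arcs.items():
        if u in (fn.source, fn.sink) or v in (fn.source, fn.sink):
            continue
        base.add_edge(u, v, **{TOM_ATTR: c})
    for n in fn.nodes - {fn.source, fn.sink}:
        base.add_node(n)
    return base


def write_maxnet_tsv(fn: FlowNetwork, path: str | Path) -> None:
    """Debug dump as TSV (from, to, capacity)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# from\tto\tcapacity\n")
        for (u, v), c in sorted(fn.arcs.items()):
            fh.write(f"{u}\t{v}\t{c:.8g}\n")


def write_dimacs(fn: FlowNetwork, path: str | Path) -> None:
    """Export in DIMACS max-flow format for cross-validation with external solvers.

    Real capacities are written as-is; DIMACS traditionally uses integers,
    so consumers needing integral capacities should scale first.
    """
    order = sorted(fn.nodes)
    index = {n: i + 1 for i, n in enumerate(order)}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"c node ids: {' '.join(order)}\n")
        fh.write(f"p max {len(order)} {len(fn.arcs)}\n")
        fh.write(f"n {index[fn.source]} s\n")
        fh.write(f"n {index[fn.sink]} t\n")
        for (u, v), c in sorted(fn.arcs.items()):
            fh.write(f"a {index[u]} {index[v]} {c:.10g}\n")
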