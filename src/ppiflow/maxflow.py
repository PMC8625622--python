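"""Maximum-flow solvers: FIFO push-relabel plus an augmenting-path oracle.

The production solver is a from-scratch push-relabel implementation. Every
node carries a height and an excess; flow is pushed only along residual arcs
that step exactly one height level down, and a node with excess but no
admissible arc is relabelled to one above its lowest residual neighbour.
Active nodes are discharged in FIFO order with current-arc pointers, giving
the classic O(V^3) bound and deterministic output for a fixed arc order
(arcs are sorted lexicographically by (from, to)).

``reference_maxflow`` is an independent Edmonds-Karp (BFS augmenting path)
solver used as a testing oracle; it shares nothing with the push-relabel
code path beyond the arc indexing helpers.

Capacities are nonnegative reals (TOM weights), so all comparisons use an
epsilon (default 1e-12) below which excess and residuals are treated as zero.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

from .maxnet import FlowNetwork

EPSILON = 1e-12


@dataclass
class FlowResult:
    """A feasible (maximum) flow on a FlowNetwork.

    ``arc_flow`` maps each original arc to its flow; ``node_outflow`` maps
    each source-adjacent node to the flow on its source arc (by conservation,
    the node's net forward throughput); ``residual_reachable`` is the
    source side of a minimum cut.
    """

    arc_flow: dict[tuple[str, str], float]
    total_flow: float
    node_outflow: dict[str, float]
    residual_reachable: set[str] = field(default_factory=set)


class _ArcStore:
    """Indexed residual-graph representation shared by both solvers.

    Each input arc becomes a forward entry with residual capacity and a
    paired reverse entry of residual 0; antiparallel input arcs stay
    distinct (no merging). Arcs are inserted in lexicographic (from, to)
    order for reproducibility.
    """

    def __init__(self, fn: FlowNetwork):
        if fn.source == fn.sink:
            raise ValueError("source and sink must differ")
        self.nodes = sorted(fn.nodes)
        self.index = {n: i for i, n in enumerate(self.nodes)}
        if fn.source not in self.index or fn.sink not in self.index:
            raise ValueError("source/sink missing from node set")
        self.s = self.index[fn.source]
        self.t = self.index[fn.sink]
        n = len(self.nodes)
        self.head: list[list[int]] = [[] for _ in range(n)]  # arc ids per node
        self.to: list[int] = []
        self.res: list[float] = []  # residual capacity
        self.cap: list[float] = []  # original capacity (0 for reverse arcs)
        self.orig: list[tuple[str, str] | None] = []
        for (u, v), c in sorted(fn.arcs.items()):
            if c < 0:
                raise ValueError(f"negative capacity on arc {u!r}->{v!r}")
            ui, vi = self.index[u], self.index[v]
            self._add(ui, vi, c, (u, v))

    def _add(self, u: int, v: int, c: float, orig: tuple[str, str]) -> None:
        self.head[u].append(len(self.to))
        self.to.append(v)
        self.res.append(c)
        self.cap.append(c)
        self.orig.append(orig)
        self.head[v].append(len(self.to))
        self.to.append(u)
        self.res.append(0.0)
        self.cap.append(0.0)
        self.orig.append(None)

    def flow_of(self, arc_id: int) -> float:
        # forward arcs sit at even ids; flow = cap - residual
        return self.cap[arc_id] - self.res[arc_id]

    def result(self, fn: FlowNetwork, epsilon: float) -> FlowResult:
        arc_flow: dict[tuple[str, str], float] = {}
        for a in range(0, len(self.to), 2):
            f = self.flow_of(a)
            arc_flow[self.orig[a]] = f if f > epsilon else 0.0
        total = sum(f for (u, _), f in arc_flow.items() if u == fn.source)
        node_outflow = {v: f for (u, v), f in arc_flow.items() if u == fn.source}
        # source side of a minimum cut: residual BFS from the source
        seen = {self.s}
        queue = deque([self.s])
        while queue:
            u = queue.popleft()
            for a in self.head[u]:
                v = self.to[a]
                if v not in seen and self.res[a] > epsilon:
                    seen.add(v)
                    queue.append(v)
        reachable = {self.nodes[i] for i in seen}
        return FlowResult(arc_flow=arc_flow, total_flow=total, node_outflow=node_outflow, residual_reachable=reachable)


def push_relabel_maxflow(fn: FlowNetwork, epsilon: float = EPSILON) -> FlowResult:
    """Solve maximum flow with FIFO push-relabel.

    Returns a maximum flow: capacity and conservation constraints hold, and
    no augmenting source-sink path remains in the residual graph (so the
    value equals a minimum cut by max-flow/min-cut duality).
    """
    store = _ArcStore(fn)
    n = len(store.nodes)
    s, t = store.s, store.t
    height = [0] * n
    height[s] = n
    excess = [0.0] * n
    current = [0] * n  # current-arc pointer per node

    active: deque[int] = deque()
    in_queue = [False] * n

    def push(a: int, u: int, v: int, amount: float) -> None:
        store.res[a] -= amount
        store.res[a ^ 1] += amount
        excess[u] -= amount
        excess[v] += amount
        if v not in (s, t) and not in_queue[v] and excess[v] > epsilon:
            in_queue[v] = True
            active.append(v)

    # saturate all source arcs
    for a in store.head[s]:
        if a % 2 == 0 and store.res[a] > epsilon:
            push(a, s, store.to[a], store.res[a])

    while active:
        u = active.popleft()
        in_queue[u] = False
        # discharge u completely
        while excess[u] > epsilon:
            if current[u] == len(store.head[u]):
                # relabel: one above the lowest residual neighbour
                min_h = None
                for a in store.head[u]:
                    if store.res[a] > epsilon:
                        hv = height[store.to[a]]
                        if min_h is None or hv < min_h:
                            min_h = hv
                if min_h is None:
                    break  # no residual arc at all; excess is stranded (cannot happen for preflows)
                height[u] = min_h + 1
                current[u] = 0
            else:
                a = store.head[u][current[u]]
                v = store.to[a]
                if store.res[a] > epsilon and height[u] == height[v] + 1:
                    push(a, u, v, min(excess[u], store.res[a]))
                else:
                    current[u] += 1

    return store.result(fn, epsilon)


def reference_maxflow(fn: FlowNetwork, epsilon: float = EPSILON) -> FlowResult:
    """Edmonds-Karp (shortest augmenting path) maximum flow, for cross-checking.

    Independent of the push-relabel code path; intended for networks up to
    roughly 10^4 arcs.
    """
    store = _ArcStore(fn)
    s, t = store.s, store.t
    n = len(store.nodes)
    while True:
        # BFS for a shortest residual s->t path
        parent_arc = [-1] * n
        parent_arc[s] = -2
        queue = deque([s])
        while queue and parent_arc[t] == -1:
            u = queue.popleft()
            for a in store.head[u]:
                v = store.to[a]
                if parent_arc[v] == -1 and store.res[a] > epsilon:
                    parent_arc[v] = a
                    queue.append(v)
        if parent_arc[t] == -1:
            break
        # bottleneck along the path
        bottleneck = float("inf")
        v = t
        while v != s:
            a = parent_arc[v]
            bottleneck = min(bottleneck, store.res[a])
            v = store.to[a ^ 1]
        v = t
        while v != s:
            a = parent_arc[v]
            store.res[a] -= bottleneck
            store.res[a ^ 1] += bottleneck
            v = store.to[a ^ 1]
    return store.result(fn, epsilon)


def node_outflows(fr: FlowResult, fn: FlowNetwork, nodes) -> dict[str, float]:
    """Per-target throughput: the flow on the source arc of each given node."""
    out: dict[str, float] = {}
    for t in sorted(nodes.ids if hasattr(nodes, "ids") else nodes):
        key = (fn.source, t)
        if key not in fn.arcs:
            raise KeyError(f"node {t!r} has no source arc in this flow network")
        out[t] = fr.arc_flow.get(key, 0.0)
    return out


def check_flow(fn: FlowNetwork, fr: FlowResult, epsilon: float = 1e-9) -> None:
    """Assert capacity and conservation constraints; raises AssertionError on violation."""
    inflow: dict[str, float] = {n: 0.0 for n in fn.nodes}
    outflow: dict[str, float] = {n: 0.0 for n in fn.nodes}
    for (u, v), c in fn.arcs.items():
        f = fr.arc_flow.get((u, v), 0.0)
        assert -epsilon <= f <= c + epsilon, f"capacity violated on {u}->{v}: {f} > {c}"
        outflow[u] += f
        inflow[v] += f
    for node in fn.nodes:
        if node in (fn.source, fn.sink):
            continue
        assert abs(inflow[node] - outflow[node]) <= epsilon, f"conservation violated at {node}"
    assert abs(outflow[fn.source] - inflow[fn.sink]) <= epsilon
    assert abs(fr.total_flow - outflow[fn.source]) <= epsilon


def read_dimacs(path: str | Path) -> FlowNetwork:
    """Read a DIMACS max-flow file (``p max``, ``n``, ``a`` lines).

    Node IDs in the comment header written by :func:`ppiflow.maxnet.write_dimacs`
    are ignored; numeric DIMACS IDs are used as node names.
    """
    source = sink = None
    arcs: dict[tuple[str, str], float] = {}
    n_nodes = 0
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("c"):
                continue
            parts = line.split()
            if parts[0] == "p":
                if len(parts) != 4 or parts[1] != "max":
                    raise ValueError(f"{path}:{lineno}: expected 'p max <n> <m>'")
                n_nodes = int(parts[2])
            elif parts[0] == "n":
                if parts[2] == "s":
                    source = parts[1]
                elif parts[2] == "t":
                    sink = parts[1]
            elif parts[0] == "a":
                u, v, c = parts[1], parts[2], float(parts[3])
                arcs[(u, v)] = arcs.get((u, v), 0.0) + c
    if source is None or sink is None:
        raise ValueError(f"{path}: missing source/sink designators")
    nodes = {str(i) for i in range(1, n_nodes + 1)} | {u for u, _ in arcs} | {v for _, v in arcs}
    return FlowNetwork(nodes=nodes, arcs=arcs, source=source, sink=sink)


def write_flow_tsv(fn: FlowNetwork, fr: FlowResult, path: str | Path) -> None:
    """Dump the solved flow as TSV (from, to, flow, capacity)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# from\tto\tflow\tcapacity\n")
        for (u, v), c in sorted(fn.arcs.items()):
            fh.write(f"{u}\t{v}\t{fr.arc_flow.get((u, v), 0.0):.8g}\t{c:.8g}\n")
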