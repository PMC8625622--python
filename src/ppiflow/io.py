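"""Reading, writing and validating the pipeline's file formats.

All inputs are plain text: an undirected interaction network as a
tab-separated edge list (two or more columns, ``#`` comments), node sets as
one ID per line, and drug-target interactions as a two-column TSV. Node IDs
are case-sensitive opaque strings; no symbol normalisation is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

log = logging.getLogger(__name__)

#: Role tags for node sets.
ROLE_DRUG_TARGET = "drug_target"
ROLE_RISK_GENE = "risk_gene"
_VALID_ROLES = frozenset({ROLE_DRUG_TARGET, ROLE_RISK_GENE})


class NetworkFormatError(ValueError):
    """A malformed input file (bad line, empty file, empty mapping)."""


@dataclass(frozen=True)
class NodeSet:
    """A role-tagged set of node IDs (drug targets or disease risk genes)."""

    role: str
    ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.role not in _VALID_ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {sorted(_VALID_ROLES)}")

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class DrugTargetMap:
    """Bipartite drug-target interactions as a deduplicated pair set."""

    pairs: frozenset[tuple[str, str]]

    def drugs(self) -> set[str]:
        return {d for d, _ in self.pairs}

    def targets_of(self, drug: str) -> set[str]:
        return {t for d, t in self.pairs if d == drug}

    def by_drug(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for d, t in self.pairs:
            out.setdefault(d, set()).add(t)
        return out

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class NetworkStats:
    """Descriptive statistics of an interaction network.

    ``n_triangles`` counts each unordered triangle once;
    ``n_triangle_incidences`` is the sum over nodes of triangles through each
    node, i.e. exactly three times ``n_triangles``. Both conventions are
    reported because published network tables are ambiguous about which one
    they print.
    """

    n_nodes: int
    n_edges: int
    transitivity: float
    avg_clustering: float
    edge_density: float
    avg_degree: float
    n_triangles: int
    n_triangle_incidences: int
    degree_histogram: dict[int, int]

    def as_rows(self) -> list[tuple[str, object]]:
        return [
            ("Number of nodes", self.n_nodes),
            ("Number of edges", self.n_edges),
            ("Transitivity", round(self.transitivity, 6)),
            ("Average clustering coefficient", round(self.avg_clustering, 6)),
            ("Edge density", round(self.edge_density, 6)),
            ("Average degree", round(self.avg_degree, 2)),
            ("Total triangles (unique)", self.n_triangles),
            ("Total triangles (3x, node incidences)", self.n_triangle_incidences),
        ]


def _data_lines(path: str | Path):
    """Yield (line_number, stripped_line) skipping blanks and '#' comments."""
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read an undirected interaction network from a 2+ column TSV.

    Duplicate lines and reversed duplicates collapse onto a single undirected
    edge. Self-loops are dropped with a warning but their node is kept.
    Columns beyond the first two are ignored (SIF-like dialects tolerated).

    Raises
    ------
    NetworkFormatError
        If a data line has fewer than two tab-separated fields, or the file
        contains no data lines.
    """
    net = nx.Graph()
    n_self_loops = 0
    n_lines = 0
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise NetworkFormatError(f"{path}:{lineno}: expected >=2 tab-separated fields, got {line!r}")
        u, v = fields[0], fields[1]
        n_lines += 1
        if u == v:
            n_self_loops += 1
            net.add_node(u)
            continue
        net.add_edge(u, v)
    if n_lines == 0:
        raise NetworkFormatError(f"{path}: no interactions found (empty network)")
    if n_self_loops:
        log.warning("%s: dropped %d self-loop(s)", path, n_self_loops)
    log.info("%s: %d lines -> %d nodes, %d edges", path, n_lines, net.number_of_nodes(), net.number_of_edges())
    return net


def write_edge_list(net: nx.Graph, path: str | Path) -> None:
    """Write an edge list as TSV with edges canonicalised (sorted endpoints, sorted lines)."""
    rows = sorted(tuple(sorted(e)) for e in net.edges())
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# node1\tnode2\n")
        for u, v in rows:
            fh.write(f"{u}\t{v}\n")


def read_node_set(path: str | Path, role: str) -> NodeSet:
    """Read a one-ID-per-line node list; blank lines ignored, IDs deduplicated."""
    ids = {line.strip() for _, line in _data_lines(path)}
    ids.discard("")
    if not ids:
        raise NetworkFormatError(f"{path}: empty node set")
    return NodeSet(role=role, ids=frozenset(ids))


def write_node_set(ns: NodeSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i in sorted(ns.ids):
            fh.write(i + "\n")


def map_to_network(ns: NodeSet, net: nx.Graph) -> NodeSet:
    """Restrict a node set to the IDs actually present in the network.

    Mirrors the bookkeeping of mapping externally curated gene lists onto an
    interactome (kept/dropped counts are logged). An empty intersection is an
    error: the flow construction cannot anchor on zero nodes.
    """
    kept = frozenset(i for i in ns.ids if i in net)
    dropped = len(ns.ids) - len(kept)
    log.info("mapped %s: kept %d, dropped %d (not in network)", ns.role, len(kept), dropped)
    if not kept:
        raise NetworkFormatError(f"no {ns.role} IDs present in the network ({len(ns.ids)} supplied)")
    return NodeSet(role=ns.role, ids=kept)


def read_dti(path: str | Path) -> DrugTargetMap:
    """Read drug-target interactions from a two-column TSV (drug, target)."""
    pairs: set[tuple[str, str]] = set()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise NetworkFormatError(f"{path}:{lineno}: expected 2 tab-separated fields, got {line!r}")
        pairs.add((fields[0], fields[1]))
    if not pairs:
        raise NetworkFormatError(f"{path}: no drug-target pairs found")
    return DrugTargetMap(pairs=frozenset(pairs))


def write_dti(dti: DrugTargetMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# drug_id\ttarget_id\n")
        for d, t in sorted(dti.pairs):
            fh.write(f"{d}\t{t}\n")


def average_degree(n_nodes: int, n_edges: int) -> float:
    """Mean degree 2E/N, computed with exact integer arithmetic before division."""
    if n_nodes <= 0:
        raise ValueError("n_nodes must be positive")
    return (2 * n_edges) / n_nodes


def network_stats(net: nx.Graph) -> NetworkStats:
    """Descriptive statistics of an undirected network.

    Transitivity is the global clustering coefficient 3T / (connected
    triples); average clustering is the mean of local coefficients with
    degree<2 nodes contributing 0; density is E / (N choose 2).
    """
    n = net.number_of_nodes()
    if n == 0:
        raise NetworkFormatError("cannot compute statistics of an empty network")
    m = net.number_of_edges()
    tri_per_node = nx.triangles(net)
    incidences = sum(tri_per_node.values())
    hist: dict[int, int] = {}
    for _, deg in net.degree():
        hist[deg] = hist.get(deg, 0) + 1
    return NetworkStats(
        n_nodes=n,
        n_edges=m,
        transitivity=nx.transitivity(net),
        avg_clustering=nx.average_clustering(net),
        edge_density=nx.density(net),
        avg_degree=average_degree(n, m),
        n_triangles=incidences // 3,
        n_triangle_incidences=incidences,
        degree_histogram=hist,
    )


def write_stats(stats: NetworkStats, path: str | Path) -> None:
    """Write statistics as a two-column key-value TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# property\tvalue\n")
        for key, value in stats.as_rows():
            fh.write(f"{key}\t{value}\n")
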