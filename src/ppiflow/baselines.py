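"""Centrality baselines: degree, closeness, betweenness, PageRank, and
random walk with restart.

These rank the same drug targets from the same interaction network, but by
topological importance instead of flow toward the risk genes, and feed the
identical best-target drug-ranking rule. Degree, closeness, betweenness and
PageRank run on the unweighted graph; random walk with restart is seeded
from the risk-gene set, which is the only baseline that sees the disease.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .io import DrugTargetMap, NodeSet
from .prioritize import DrugRanking, rank_drugs, rank_targets

METHODS = ("degree", "closeness", "betweenness", "random_walk", "pagerank")


@dataclass(frozen=True)
class CentralityScores:
    """Nonnegative per-node scores produced by one ranking method."""

    method: str
    scores: dict[str, float]


def _require_nonempty(net: nx.Graph) -> None:
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")


def degree_centrality(net: nx.Graph) -> CentralityScores:
    """Raw (unnormalised) degree of each node."""
    _require_nonempty(net)
    return CentralityScores("degree", {n: float(d) for n, d in net.degree()})


def closeness_centrality(net: nx.Graph) -> CentralityScores:
    """Closeness with the Wasserman-Faust correction for disconnected graphs.

    score(v) = (r-1)/sum_d * (r-1)/(n-1), where r is the size of v's
    reachable set; isolated nodes score 0.
    """
    _require_nonempty(net)
    return CentralityScores("closeness", dict(nx.closeness_centrality(net, wf_improved=True)))


def betweenness_centrality(net: nx.Graph) -> CentralityScores:
    """Unnormalised shortest-path betweenness (endpoints excluded)."""
    _require_nonempty(net)
    return CentralityScores("betweenness", dict(nx.betweenness_centrality(net, normalized=False)))


def pagerank(net: nx.Graph, damping: float = 0.85, tol: float = 1e-10, max_iter: int = 1000) -> CentralityScores:
    """PageRank of the undirected graph (each edge walked both ways); sums to 1."""
    _require_nonempty(net)
    if not 0 < damping < 1:
        raise ValueError("damping must be in (0, 1)")
    try:
        scores = nx.pagerank(net, alpha=damping, tol=tol, max_iter=max_iter)
    except nx.PowerIterationFailedConvergence as exc:
        raise RuntimeError(f"PageRank did not converge in {max_iter} iterations") from exc
    return CentralityScores("pagerank", dict(scores))


def random_walk_restart(
    net: nx.Graph,
    restart_set: NodeSet,
    restart_prob: float = 0.5,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> CentralityScores:
    """Stationary distribution of a restarting walk seeded at the risk genes.

    At each step the walker teleports to a uniformly random node of
    ``restart_set`` with probability ``restart_prob``, else moves to a
    uniform neighbour. A walker stranded on a degree-0 node always restarts.
    Solves p = r e + (1-r) W p by power iteration; the result sums to 1.
    """
    _require_nonempty(net)
    if not 0 < restart_prob < 1:
        raise ValueError("restart_prob must be in (0, 1)")
    nodes = sorted(net.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    seeds = [index[n] for n in restart_set.ids if n in index]
    if not seeds:
        raise ValueError("restart set is disjoint from the network")
    n = len(nodes)
    # column-stochastic transition matrix W[j, i] = P(i -> j)
    rows, cols, vals = [], [], []
    dangling = np.zeros(n, dtype=bool)
    for u in nodes:
        i = index[u]
        nbrs = list(net[u])
        if not nbrs:
            dangling[i] = True
            continue
        p = 1.0 / len(nbrs)
        for v in nbrs:
            rows.append(index[v])
            cols.append(i)
            vals.append(p)
    W = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    e = np.zeros(n)
    e[seeds] = 1.0 / len(seeds)
    r = restart_prob
    p = e.copy()
    for _ in range(max_iter):
        stranded = p[dangling].sum()
        nxt = r * e + (1 - r) * (W @ p) + (1 - r) * stranded * e
        err = np.abs(nxt - p).sum()
        p = nxt
        if err < tol:
            break
    else:
        raise RuntimeError(f"random walk with restart did not converge in {max_iter} iterations")
    p = p / p.sum()
    return CentralityScores("random_walk", {nodes[i]: float(p[i]) for i in range(n)})


def rank_by_centrality(cs: CentralityScores, targets: NodeSet, dti: DrugTargetMap, agg: str = "max") -> DrugRanking:
    """Restrict scores to the drug targets and rank drugs by the best-target rule."""
    restricted = {t: cs.scores[t] for t in targets.ids if t in cs.scores}
    if not restricted:
        raise ValueError("no drug target has a centrality score")
    return rank_drugs(rank_targets(restricted), dti, agg=agg)
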