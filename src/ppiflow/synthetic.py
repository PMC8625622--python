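"""Reproducible synthetic fixtures: scale-free interactomes with planted roles.

Real protein-interaction networks are hub-dominated — a few proteins have
very many partners while most have few — so the generator uses preferential
attachment: starting from a small clique, each new node attaches to
``attachment_edges`` distinct existing nodes with probability proportional
to their current degree. On top of the network the generator plants

* a *risk-gene* module (one graph neighbourhood, mimicking the tendency of
  disease genes to cluster),
* a disjoint set of *drug targets* sampled uniformly elsewhere, and
* ``n_drivers`` of those targets wired with ``driver_boost`` extra edges
  into the risk module, making them genuinely high-flow routes to the sink,

plus a bipartite drug-target map in which every planted driver is covered by
at least one drug. All randomness flows from the single ``seed`` through one
named generator; a fixed seed gives byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import networkx as nx
import numpy as np

from .io import (
    ROLE_DRUG_TARGET,
    ROLE_RISK_GENE,
    DrugTargetMap,
    NodeSet,
    write_dti,
    write_edge_list,
    write_node_set,
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic study.

    Defaults give a 500-node hub-dominated network with 50 drug targets,
    50 risk genes, 5 boosted drivers and 100 drugs carrying 1-3 targets each.
    """

    n_nodes: int = 500
    attachment_edges: int = 3
    n_targets: int = 50
    n_risk_genes: int = 50
    n_drivers: int = 5
    n_drugs: int = 100
    targets_per_drug: tuple[int, int] = (1, 3)
    driver_boost: int = 10
    seed: int = 0

    def validate(self) -> None:
        m = self.attachment_edges
        if self.n_nodes < m + 1 or m < 1:
            raise ValueError("need n_nodes >= attachment_edges + 1 >= 2")
        if self.n_drivers > self.n_targets:
            raise ValueError("n_drivers cannot exceed n_targets")
        if self.n_targets + self.n_risk_genes > self.n_nodes:
            raise ValueError("target and risk-gene sets cannot cover more than all nodes")
        lo, hi = self.targets_per_drug
        if not 1 <= lo <= hi <= self.n_targets:
            raise ValueError("targets_per_drug range must satisfy 1 <= lo <= hi <= n_targets")
        if self.driver_boost < 0:
            raise ValueError("driver_boost must be >= 0")
        if self.driver_boost > self.n_risk_genes:
            raise ValueError("driver_boost cannot exceed n_risk_genes (not enough distinct risk genes to wire to)")


def _node_name(i: int) -> str:
    return f"G{i:05d}"


def generate_network(spec: SyntheticSpec) -> nx.Graph:
    """Preferential-attachment graph on ``n_nodes`` labelled G00000, G00001, ...

    Starts from a clique on ``attachment_edges + 1`` nodes, so the edge count
    is exactly C(m+1, 2) + (n - m - 1) * m. The result is connected with a
    heavy-tailed degree distribution.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    m = spec.attachment_edges
    net = nx.Graph()
    core = [_node_name(i) for i in range(m + 1)]
    net.add_nodes_from(core)
    for i, u in enumerate(core):
        for v in core[i + 1 :]:
            net.add_edge(u, v)
    # repeated-nodes list: each node appears once per unit of degree
    repeated: list[str] = [u for u in core for _ in range(m)]
    for i in range(m + 1, spec.n_nodes):
        new = _node_name(i)
        chosen: set[str] = set()
        while len(chosen) < m:
            chosen.add(repeated[rng.integers(len(repeated))])
        for u in sorted(chosen):
            net.add_edge(new, u)
            repeated.append(u)
        repeated.extend([new] * m)
    return net


def plant_roles(net: nx.Graph, spec: SyntheticSpec) -> tuple[NodeSet, NodeSet, frozenset[str]]:
    """Plant risk-gene, target and driver roles; mutates ``net`` in place.

    Risk genes form one connected *peripheral* community: the module is
    seeded at a minimum-degree node and grown by repeatedly absorbing the
    lowest-degree frontier neighbour. Disease risk genes from association
    studies are rarely the interactome's hubs, and a hub-centred module
    would be trivially reachable from everywhere, washing out the flow
    competition the benchmark is meant to probe. Targets are sampled
    uniformly from the remaining nodes; the first ``n_drivers`` targets (by
    the generator's draw) each gain ``driver_boost`` new edges to distinct
    risk genes they were not already adjacent to. Returns
    (targets, risk_genes, drivers).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + 1)
    nodes = sorted(net.nodes())
    if spec.n_targets + spec.n_risk_genes > len(nodes):
        raise ValueError("network too small for the requested role counts")

    # peripheral module: seed at a random minimum-degree node, grow by
    # lowest-degree frontier expansion (ties broken lexicographically)
    degree = dict(net.degree())
    min_deg = min(degree.values())
    seed_pool = [n for n in nodes if degree[n] == min_deg]
    seed_node = seed_pool[rng.integers(len(seed_pool))]
    module: set[str] = {seed_node}
    frontier = {v for v in net[seed_node]}
    while len(module) < spec.n_risk_genes:
        if not frontier:
            raise ValueError("network too fragmented to host the risk-gene module")
        pick = min(frontier, key=lambda v: (degree[v], v))
        frontier.discard(pick)
        module.add(pick)
        frontier.update(v for v in net[pick] if v not in module)
    risk = frozenset(module)

    remaining = [n for n in nodes if n not in risk]
    idx = rng.choice(len(remaining), size=spec.n_targets, replace=False)
    target_list = [remaining[i] for i in idx]
    targets = frozenset(target_list)
    drivers = frozenset(target_list[: spec.n_drivers])

    risk_sorted = sorted(risk)
    for d in sorted(drivers):
        candidates = [g for g in risk_sorted if not net.has_edge(d, g) and g != d]
        k = min(spec.driver_boost, len(candidates))
        if k < spec.driver_boost:
            raise ValueError(f"driver {d} cannot receive {spec.driver_boost} new edges into the risk module")
        if k:
            pick = rng.choice(len(candidates), size=k, replace=False)
            for j in pick:
                net.add_edge(d, candidates[j])

    return (
        NodeSet(role=ROLE_DRUG_TARGET, ids=targets),
        NodeSet(role=ROLE_RISK_GENE, ids=risk),
        drivers,
    )


def generate_dti(targets: NodeSet, spec: SyntheticSpec, drivers: frozenset[str] = frozenset()) -> DrugTargetMap:
    """Bipartite drug-target map D00000..; every driver gets at least one drug.

    Driver-covering targets are attached to randomly chosen drug IDs (not the
    first IDs) so that lexicographic tie-breaking downstream cannot
    systematically favour driver drugs.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + 2)
    target_list = sorted(targets.ids)
    lo, hi = spec.targets_per_drug
    drugs = [f"D{i:05d}" for i in range(spec.n_drugs)]
    pairs: set[tuple[str, str]] = set()
    for drug in drugs:
        k = int(rng.integers(lo, hi + 1))
        idx = rng.choice(len(target_list), size=k, replace=False)
        for i in idx:
            pairs.add((drug, target_list[i]))
    # guarantee coverage of every driver via a random drug each
    covered = {t for _, t in pairs}
    for d in sorted(drivers):
        if d not in covered:
            drug = drugs[rng.integers(len(drugs))]
            pairs.add((drug, d))
    return DrugTargetMap(pairs=frozenset(pairs))


def driver_drugs(dti: DrugTargetMap, drivers: frozenset[str]) -> set[str]:
    """Drugs targeting at least one planted driver (the benchmark's ground truth)."""
    return {d for d, t in dti.pairs if t in drivers}


def make_fixture(spec: SyntheticSpec, out_dir: str | Path) -> dict[str, Path]:
    """Generate a complete toy study directory readable by the io module.

    Writes network.tsv, targets.txt, risk_genes.txt, dti.tsv and drivers.txt
    (ground truth) and returns the paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net = generate_network(spec)
    targets, risk, drivers = plant_roles(net, spec)
    dti = generate_dti(targets, spec, drivers)
    paths = {
        "network": out / "network.tsv",
        "targets": out / "targets.txt",
        "risk_genes": out / "risk_genes.txt",
        "dti": out / "dti.tsv",
        "drivers": out / "drivers.txt",
    }
    write_edge_list(net, paths["network"])
    write_node_set(targets, paths["targets"])
    write_node_set(risk, paths["risk_genes"])
    write_dti(dti, paths["dti"])
    with open(paths["drivers"], "w", encoding="utf-8") as fh:
        for d in sorted(drivers):
            fh.write(d + "\n")
    return paths
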