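"""Centrality baselines against brute-force and dense linear-algebra oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from ppiflow import baselines
from ppiflow.io import ROLE_DRUG_TARGET, ROLE_RISK_GENE, DrugTargetMap, NodeSet


def labelled(g):
    return nx.relabel_nodes(g, {i: f"g{i}" for i in g})


class TestDegree:
    def test_star(self, star4):
        s = baselines.degree_centrality(star4).scores
        assert s["C"] == 4 and all(s[f"L{i}"] == 1 for i in range(1, 5))

    def test_triangle(self, triangle):
        assert set(baselines.degree_centrality(triangle).scores.values()) == {2.0}


class TestCloseness:
    def test_star_hand_values(self, star4):
        s = baselines.closeness_centrality(star4).scores
        assert s["C"] == pytest.approx(1.0)
        assert s["L1"] == pytest.approx(4 / 7)

    def test_isolated_node_scores_zero(self):
        g = nx.Graph([("a", "b")])
        g.add_node("z")
        assert baselines.closeness_centrality(g).scores["z"] == 0.0

    def test_complete_graph_all_one(self):
        g = labelled(nx.complete_graph(6))
        assert all(v == pytest.approx(1.0) for v in baselines.closeness_centrality(g).scores.values())

    @pytest.mark.parametrize("seed", [0, 3])
    def test_matches_all_pairs_bfs_oracle(self, seed):
        g = labelled(nx.gnp_random_graph(40, 0.08, seed=seed))
        scores = baselines.closeness_centrality(g).scores
        n = g.number_of_nodes()
        for v in g:
            dist = nx.single_source_shortest_path_length(g, v)
            reach = len(dist) - 1
            total = sum(dist.values())
            expected = 0.0 if total == 0 else (reach / total) * (reach / (n - 1))
            assert scores[v] == pytest.approx(expected, abs=1e-12)


class TestBetweenness:
    def test_path_intermediate(self, path3):
        s = baselines.betweenness_centrality(path3).scores
        assert s["B"] == pytest.approx(1.0) and s["A"] == s["C"] == 0.0

    def test_triangle_all_zero(self, triangle):
        assert set(baselines.betweenness_centrality(triangle).scores.values()) == {0.0}

    def test_matches_brute_force_path_enumeration(self):
        g = labelled(nx.gnp_random_graph(12, 0.3, seed=2))
        scores = baselines.betweenness_centrality(g).scores
        nodes = sorted(g)
        expected = dict.fromkeys(nodes, 0.0)
        for s, t in itertools.combinations(nodes, 2):
            try:
                paths = list(nx.all_shortest_paths(g, s, t))
            except nx.NetworkXNoPath:
                continue
            for v in nodes:
                if v in (s, t):
                    continue
                expected[v] += sum(1 for p in paths if v in p) / len(paths)
        for v in nodes:
            assert scores[v] == pytest.approx(expected[v], abs=1e-9)


def pagerank_linear_solve(g: nx.Graph, damping: float) -> dict[str, float]:
    """Direct solve of (I - d W) p = (1-d)/n on the column-stochastic walk matrix."""
    nodes = sorted(g)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    W = np.zeros((n, n))
    for u in nodes:
        nbrs = list(g[u])
        if not nbrs:
            W[:, idx[u]] = 1.0 / n  # dangling: uniform
            continue
        for v in nbrs:
            W[idx[v], idx[u]] = 1.0 / len(nbrs)
    p = np.linalg.solve(np.eye(n) - damping * W, np.full(n, (1 - damping) / n))
    p /= p.sum()
    return {v: p[idx[v]] for v in nodes}


class TestPagerank:
    def test_ring_is_uniform(self):
        g = labelled(nx.cycle_graph(8))
        scores = baselines.pagerank(g).scores
        assert all(v == pytest.approx(1 / 8, abs=1e-12) for v in scores.values())

    def test_two_disconnected_pairs_uniform(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        scores = baselines.pagerank(g).scores
        assert all(v == pytest.approx(0.25, abs=1e-9) for v in scores.values())

    def test_matches_dense_linear_solve(self):
        g = labelled(nx.gnp_random_graph(25, 0.15, seed=8))
        scores = baselines.pagerank(g, damping=0.85).scores
        expected = pagerank_linear_solve(g, 0.85)
        for v in g:
            assert scores[v] == pytest.approx(expected[v], abs=1e-7)

    def test_sums_to_one_and_damping_validated(self):
        g = labelled(nx.gnp_random_graph(30, 0.1, seed=1))
        assert sum(baselines.pagerank(g).scores.values()) == pytest.approx(1.0, abs=1e-9)
        with pytest.raises(ValueError):
            baselines.pagerank(g, damping=1.5)


class TestRandomWalkRestart:
    def rwr_linear_solve(self, g, seeds, r):
        nodes = sorted(g)
        n = len(nodes)
        idx = {v: i for i, v in enumerate(nodes)}
        W = np.zeros((n, n))
        e = np.zeros(n)
        for s in seeds:
            e[idx[s]] = 1 / len(seeds)
        for u in nodes:
            nbrs = list(g[u])
            if not nbrs:
                W[:, idx[u]] = e  # stranded walker restarts
                continue
            for v in nbrs:
                W[idx[v], idx[u]] = 1 / len(nbrs)
        p = np.linalg.solve(np.eye(n) - (1 - r) * W, r * e)
        p /= p.sum()
        return {v: p[idx[v]] for v in nodes}

    def test_high_restart_limit_concentrates_on_seeds(self):
        g = labelled(nx.path_graph(6))
        rs = NodeSet(role=ROLE_RISK_GENE, ids=frozenset({"g0", "g5"}))
        scores = baselines.random_walk_restart(g, rs, restart_prob=0.999).scores
        assert scores["g0"] == pytest.approx(0.5, abs=1e-2)
        assert scores["g5"] == pytest.approx(0.5, abs=1e-2)
        assert scores["g2"] < 0.01

    def test_symmetric_graph_symmetric_scores(self):
        g = labelled(nx.cycle_graph(6))
        rs = NodeSet(role=ROLE_RISK_GENE, ids=frozenset({"g0", "g3"}))  # antipodal seeds
        scores = baselines.random_walk_restart(g, rs).scores
        assert scores["g0"] == pytest.approx(scores["g3"], abs=1e-9)
        assert scores["g1"] == pytest.approx(scores["g2"], abs=1e-9)
        assert scores["g1"] == pytest.approx(scores["g4"], abs=1e-9)

    @pytest.mark.parametrize("r", [0.3, 0.5, 0.7])
    def test_matches_dense_linear_solve(self, r):
        g = labelled(nx.gnp_random_graph(30, 0.12, seed=6))
        seeds = {"g0", "g3", "g7"}
        rs = NodeSet(role=ROLE_RISK_GENE, ids=frozenset(seeds))
        scores = baselines.random_walk_restart(g, rs, restart_prob=r).scores
        expected = self.rwr_linear_solve(g, sorted(seeds), r)
        for v in g:
            assert scores[v] == pytest.approx(expected[v], abs=1e-8)
        assert sum(scores.values()) == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_restart_set_rejected(self, triangle):
        rs = NodeSet(role=ROLE_RISK_GENE, ids=frozenset({"ZZ"}))
        with pytest.raises(ValueError):
            baselines.random_walk_restart(triangle, rs)

    def test_invariant_to_node_relabelling(self):
        g = labelled(nx.gnp_random_graph(20, 0.2, seed=12))
        rs = NodeSet(role=ROLE_RISK_GENE, ids=frozenset({"g1", "g4"}))
        base = baselines.random_walk_restart(g, rs).scores
        mapping = {v: f"x{v}" for v in g}
        g2 = nx.relabel_nodes(g, mapping)
        rs2 = NodeSet(role=ROLE_RISK_GENE, ids=frozenset({"xg1", "xg4"}))
        permuted = baselines.random_walk_restart(g2, rs2).scores
        for v in g:
            assert base[v] == pytest.approx(permuted[mapping[v]], abs=1e-9)


class TestRankByCentrality:
    def test_star_center_drug_first(self, star4):
        cs = baselines.degree_centrality(star4)
        targets = NodeSet(role=ROLE_DRUG_TARGET, ids=frozenset({"C", "L1"}))
        dti = DrugTargetMap(pairs=frozenset({("Dcenter", "C"), ("Dleaf", "L1")}))
        dr = baselines.rank_by_centrality(cs, targets, dti)
        assert dr.entries[0][0] == "Dcenter"

    def test_identical_scores_lexicographic_drug_order(self, triangle):
        cs = baselines.degree_centrality(triangle)
        targets = NodeSet(role=ROLE_DRUG_TARGET, ids=frozenset({"A", "B"}))
        dti = DrugTargetMap(pairs=frozenset({("D2", "A"), ("D1", "B")}))
        dr = baselines.rank_by_centrality(cs, targets, dti)
        assert [d for d, _, _ in dr.entries] == ["D1", "D2"]

    def test_end_to_end_hand_ordering(self, path3):
        # degrees: A=1, B=2, C=1 -> drug on B first, then lexicographic
        cs = baselines.degree_centrality(path3)
        targets = NodeSet(role=ROLE_DRUG_TARGET, ids=frozenset({"A", "B", "C"}))
        dti = DrugTargetMap(pairs=frozenset({("Da", "A"), ("Db", "B"), ("Dc", "C")}))
        dr = baselines.rank_by_centrality(cs, targets, dti)
        assert [d for d, _, _ in dr.entries] == ["Db", "Da", "Dc"]
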