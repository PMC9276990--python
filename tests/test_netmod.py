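"""Network construction, cohesiveness hand cases, greedy growth against
exhaustive search, merging, and rank-test significance oracles."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from modreg.datatypes import Module, WeightedNetwork
from modreg.netmod import (
    ModuleDetectionConfig,
    build_network,
    cohesiveness,
    detect_modules,
    grow_module,
    match_score,
    merge_overlapping,
    module_significance,
)
from modreg.simulate import GroundTruth, SimulationConfig, simulate_network
from oracles import mwu_greater_enum


def _edges(*rows):
    return pd.DataFrame(rows, columns=["node_a", "node_b", "score"])


class TestBuildNetwork:
    def test_score_below_threshold_excluded(self):
        net = build_network(_edges(("A", "B", 0.39), ("B", "C", 0.41)), 0.400)
        assert not net.graph.has_edge("A", "B")
        assert net.graph.has_edge("B", "C")

    def test_disconnected_node_removed(self):
        net = build_network(_edges(("A", "B", 0.2), ("B", "C", 0.9)), 0.400)
        assert "A" not in net.graph  # its only edge was filtered

    def test_duplicates_keep_max_score(self):
        net = build_network(_edges(("A", "B", 0.5), ("B", "A", 0.7)), 0.0)
        assert net.n_edges == 1
        assert net.graph["A"]["B"]["weight"] == 0.7

    def test_malformed_rows_skipped_all_bad_rejected(self):
        net = build_network(_edges(("A", "A", 0.9), ("A", "B", "oops"),
                                   ("B", "C", 0.8)), 0.0)
        assert net.n_edges == 1
        with pytest.raises(ValueError):
            build_network(_edges(("A", "A", 0.9)), 0.0)


class TestCohesiveness:
    def test_triangle_is_one(self, triangle_network):
        assert cohesiveness(triangle_network, {"a", "b", "c"}, 0.0) == 1.0

    def test_singleton_is_zero(self, triangle_network):
        assert cohesiveness(triangle_network, {"a"}, 0.0) == 0.0

    def test_triangle_with_pendant(self, triangle_with_pendant):
        assert cohesiveness(
            triangle_with_pendant, {"a", "b", "c"}, 0.0
        ) == pytest.approx(0.75)

    def test_penalty_in_denominator(self, triangle_network):
        # 3 / (3 + 0 + 2*3) = 1/3
        assert cohesiveness(triangle_network, {"a", "b", "c"}, 2.0) == pytest.approx(1 / 3)

    def test_unknown_node_rejected(self, triangle_network):
        with pytest.raises(KeyError):
            cohesiveness(triangle_network, {"a", "zzz"}, 0.0)

    def test_internal_addition_never_decreases_at_zero_penalty(self):
        rng = np.random.default_rng(0)
        g = nx.gnp_random_graph(12, 0.5, seed=2)
        for a, b in g.edges:
            g[a][b]["weight"] = float(rng.uniform(0.1, 1.0))
        g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
        net = WeightedNetwork(g)
        nodes = sorted(g.nodes)
        members = set(nodes[:5])
        base = cohesiveness(net, members, 0.0)
        for u in nodes[5:]:
            # connected only internally = all of u's neighbors inside members
            if set(g[u]) and set(g[u]) <= members:
                assert cohesiveness(net, members | {u}, 0.0) >= base - 1e-12


def _exhaustive_best(net: WeightedNetwork, nodes, penalty: float, must_have: str):
    best, best_c = None, -1.0
    nodes = sorted(nodes)
    for r in range(1, len(nodes) + 1):
        for sub in itertools.combinations(nodes, r):
            if must_have not in sub:
                continue
            c = cohesiveness(net, set(sub), penalty)
            if c > best_c + 1e-12:
                best, best_c = set(sub), c
    return best, best_c


class TestGrowModule:
    def test_isolated_edge_is_terminal(self):
        g = nx.Graph()
        g.add_edge("u", "v", weight=1.0)
        net = WeightedNetwork(g)
        m = grow_module(net, "u", ModuleDetectionConfig(penalty=0.0))
        assert m.members == {"u", "v"}
        assert m.cohesiveness == 1.0

    def test_tie_break_adds_lexicographically_smaller(self):
        g = nx.Graph()
        g.add_edge("m", "a", weight=0.8)
        g.add_edge("m", "b", weight=0.8)
        net = WeightedNetwork(g)
        cfg = ModuleDetectionConfig(penalty=0.1)
        m = grow_module(net, "m", cfg)
        # both additions yield equal gain at the first step; 'a' must enter first
        assert "a" in m.members

    def test_recovers_planted_clique_and_matches_exhaustive(self):
        rng = np.random.default_rng(7)
        g = nx.Graph()
        clique = [f"c{i}" for i in range(8)]
        for a, b in itertools.combinations(clique, 2):
            g.add_edge(a, b, weight=1.0)
        outside = [f"x{i}" for i in range(4)]
        for x in outside:  # weak external attachments
            g.add_edge(x, clique[rng.integers(8)], weight=0.1)
        net = WeightedNetwork(g)
        cfg = ModuleDetectionConfig(penalty=2.0)
        m = grow_module(net, "c0", cfg)
        assert m.members == set(clique)
        best, best_c = _exhaustive_best(net, g.nodes, 2.0, "c0")
        assert m.cohesiveness == pytest.approx(best_c, abs=1e-12)
        assert m.members == best

    def test_result_is_local_optimum(self):
        cfg = SimulationConfig(n_genes=100, de_fraction=0.3,
                               module_sizes=(6, 6), seed=13)
        net, _ = simulate_network(cfg, _truth_for(cfg))
        det = ModuleDetectionConfig(penalty=2.0)
        for seed_node in sorted(net.graph.nodes)[:6]:
            m = grow_module(net, seed_node, det)
            assert_local_optimum(net, m, det)


def _truth_for(cfg):
    from modreg.simulate import simulate_expression

    _, truth = simulate_expression(cfg)
    return truth


def assert_local_optimum(net, module, det_cfg):
    base = cohesiveness(net, module.members, det_cfg.penalty)
    boundary = {
        u for v in module.members for u in net.graph[v]
    } - module.members
    for u in sorted(boundary):
        assert cohesiveness(net, module.members | {u}, det_cfg.penalty) <= base + 1e-9
    if module.size > 1:
        for u in module.sorted_members():
            assert cohesiveness(net, module.members - {u}, det_cfg.penalty) <= base + 1e-9


class TestMergeOverlapping:
    def _cfg(self, thr=0.8):
        return ModuleDetectionConfig(overlap_threshold=thr)

    def test_identical_modules_collapse(self, triangle_network):
        m = Module(frozenset({"a", "b", "c"}), 1.0)
        out = merge_overlapping([m, Module(frozenset({"a", "b", "c"}), 1.0)],
                                triangle_network, self._cfg())
        assert len(out) == 1

    def test_disjoint_unchanged(self, triangle_with_pendant):
        m1 = Module(frozenset({"a", "b"}), 0.5)
        m2 = Module(frozenset({"c", "d"}), 0.5)
        out = merge_overlapping([m1, m2], triangle_with_pendant, self._cfg())
        assert {m.members for m in out} == {m1.members, m2.members}

    def test_overlap_four_of_five_below_default_threshold(self):
        a = frozenset("abcde")
        b = frozenset("bcdef")
        assert match_score(a, b) == pytest.approx(16 / 25)
        g = nx.Graph()
        for x, y in itertools.combinations("abcdef", 2):
            g.add_edge(x, y, weight=1.0)
        out = merge_overlapping(
            [Module(a, 0.5), Module(b, 0.4)], WeightedNetwork(g), self._cfg(0.8)
        )
        assert len(out) == 2
        out2 = merge_overlapping(
            [Module(a, 0.5), Module(b, 0.4)], WeightedNetwork(g), self._cfg(0.6)
        )
        assert len(out2) == 1
        assert out2[0].members == a | b


class TestModuleSignificance:
    def test_clique_with_zero_boundary_matches_exact_rank_test(self):
        g = nx.complete_graph(6)
        nx.set_edge_attributes(g, 1.0, "weight")
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(6)})
        net = WeightedNetwork(g)
        m = Module(frozenset(g.nodes), 1.0)
        p, degenerate = module_significance(net, m)
        assert not degenerate
        assert p == pytest.approx(1 / math.comb(12, 6), abs=1e-15)
        assert p < 0.05

    def test_balanced_in_out_weights_degenerate(self):
        # two nodes joined internally with weight w, each with boundary w
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.6)
        g.add_edge("a", "x", weight=0.6)
        g.add_edge("b", "y", weight=0.6)
        net = WeightedNetwork(g)
        p, degenerate = module_significance(net, Module(frozenset({"a", "b"}), 0.5))
        assert degenerate
        assert p == 0.5

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(21)
        g = nx.Graph()
        members = [f"m{i}" for i in range(5)]
        for a, b in itertools.combinations(members, 2):
            if rng.random() < 0.8:
                g.add_edge(a, b, weight=float(rng.uniform(0.3, 1.0)))
        g.add_edge("m0", "out1", weight=0.9)  # boundary-dominated member
        g.add_edge("m0", "out2", weight=0.9)
        net = WeightedNetwork(g)
        m = Module(frozenset(members), 0.5)
        p, _ = module_significance(net, m)
        in_w = [sum(d["weight"] for _, u, d in g.edges(v, data=True) if u in m.members)
                for v in sorted(members)]
        out_w = [sum(d["weight"] for _, u, d in g.edges(v, data=True) if u not in m.members)
                 for v in sorted(members)]
        assert p == pytest.approx(mwu_greater_enum(np.array(in_w), np.array(out_w)),
                                  abs=1e-12)


class TestDetectModules:
    def test_recovers_planted_partition(self):
        hits = 0
        for seed in range(10):
            cfg = SimulationConfig(n_genes=2000, module_sizes=(8, 8, 8),
                                   p_within=0.9, p_between=0.02, seed=seed)
            truth = _truth_for(cfg)
            net, truth = simulate_network(cfg, truth)
            mods = detect_modules(net)
            planted = list(truth.modules().values())
            ok = len(mods) == 3 and all(
                max(len(m.members & set(pl)) / len(m.members | set(pl))
                    for pl in planted) >= 0.8
                for m in mods
            )
            hits += ok
        assert hits >= 9

    def test_empty_network_gives_empty_result(self):
        assert detect_modules(WeightedNetwork(nx.Graph())) == []

    def test_small_clique_fails_size_filter(self):
        g = nx.complete_graph(4)
        nx.set_edge_attributes(g, 1.0, "weight")
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(4)})
        assert detect_modules(WeightedNetwork(g)) == []

    def test_deterministic(self):
        cfg = SimulationConfig(n_genes=200, de_fraction=0.2,
                               module_sizes=(6, 6), seed=17)
        net, _ = simulate_network(cfg, _truth_for(cfg))
        a = detect_modules(net)
        b = detect_modules(net)
        assert [m.members for m in a] == [m.members for m in b]
        assert [m.p_value for m in a] == [m.p_value for m in b]
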