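"""Time-bounded network construction, independent-cascade influence, and paths."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from pertpath.mediators import MediatorGene
from pertpath.network import (
    TimeBoundedNetwork,
    build_time_bounded_network,
    extract_regulatory_paths,
    greedy_labeled_im,
    influence_spread,
    terminator_proteins,
)
from pertpath.subpathway import (
    DifferentialTimeVector,
    EdgeValidation,
    PerturbedSubpathway,
)


def vec(gene, vals):
    return DifferentialTimeVector(gene, np.array(vals))


def make_net(edges, labels, n_time=4):
    """edges: (u, v, p, delay) tuples."""
    g = nx.DiGraph()
    for u, v, p, d in edges:
        g.add_edge(u, v, provenance="GRN", delay=d, peak=1, p=p)
    for n, lab in labels.items():
        g.add_node(n, label=lab)
    for n in g.nodes:
        g.nodes[n].setdefault("label", "other")
    return TimeBoundedNetwork(g, n_time)


SUBPATHWAY = PerturbedSubpathway(
    "pw", 0,
    [EdgeValidation(("P1", "P2"), 1, 2, True), EdgeValidation(("P2", "P3"), 1, 1, True),
     EdgeValidation(("P3", "P4"), 1, 1, True)],
    4.0,
)


class TestBuildNetwork:
    VECTORS = {
        "X": vec("X", [1, 0, 0]),
        "M": vec("M", [0, 1, 0]),
        "G": vec("G", [0, 0, 1]),
        "P1": vec("P1", [1, 0, 0]),
        "P2": vec("P2", [0, 1, 0]),
        "P3": vec("P3", [0, 0, 1]),
        "P4": vec("P4", [0, 0, 1]),
    }

    def test_grn_pin_chain_assembled_with_delays(self):
        net = build_time_bounded_network(
            grn=[("X", "M")], pin=[("M", "G")], subpathways=[SUBPATHWAY],
            vectors=self.VECTORS, mediators=[MediatorGene("M", 1.0, 0, "tensor")],
            delay_threshold=2,
        )
        assert net.graph.has_edge("X", "M") and net.graph.has_edge("M", "G")
        assert net.graph.edges["X", "M"]["delay"] == 1
        assert net.graph.edges["M", "G"]["delay"] == 1
        assert net.graph.nodes["X"]["label"] == "TF"
        assert net.graph.nodes["M"]["label"] == "mediator"
        assert net.graph.nodes["P1"]["label"] == "pathway_gene"

    def test_reversed_timing_removes_grn_edge(self):
        vectors = dict(self.VECTORS)
        vectors["M"] = vec("M", [1, 0, 0])
        vectors["X"] = vec("X", [0, 1, 0])  # M now precedes X
        net = build_time_bounded_network(
            [("X", "M")], [], [SUBPATHWAY], vectors, delay_threshold=2
        )
        assert not net.graph.has_edge("X", "M")

    def test_simultaneous_pin_edge_kept_both_directions(self):
        vectors = dict(self.VECTORS)
        vectors["M"] = vec("M", [0, 1, 0])
        vectors["G"] = vec("G", [0, 1, 0])  # concordant, d = 0
        net = build_time_bounded_network(
            [("X", "M")], [("M", "G", 1.0)], [SUBPATHWAY], vectors, delay_threshold=2
        )
        assert net.graph.has_edge("M", "G") and net.graph.has_edge("G", "M")
        assert net.graph.edges["M", "G"]["delay"] == 0

    def test_pin_confidence_multiplies_probability(self):
        net = build_time_bounded_network(
            [], [("M", "G", 0.5)], [SUBPATHWAY], self.VECTORS, delay_threshold=2
        )
        # peak 1 over T=3 time points, scaled by confidence 0.5
        assert net.graph.edges["M", "G"]["p"] == pytest.approx(0.5 / 3)

    def test_empty_subpathways_rejected(self):
        with pytest.raises(ValueError, match="sub-pathways"):
            build_time_bounded_network([], [], [], self.VECTORS)


class TestInfluenceSpread:
    def test_deterministic_chain_counts_all_downstream(self):
        net = make_net(
            [("a", "b", 1.0, 1), ("b", "c", 1.0, 1), ("c", "d", 1.0, 1)],
            {"a": "TF"},
        )
        assert influence_spread(net, ["a"], ["b", "c", "d"], n_sim=10) == 3.0

    def test_zero_probability_spreads_only_to_seed_targets(self):
        net = make_net([("a", "b", 0.0, 1)], {"a": "TF"})
        assert influence_spread(net, ["a"], ["a", "b"], n_sim=10) == 1.0
        assert influence_spread(net, ["a"], ["b"], n_sim=10) == 0.0

    def test_two_edge_chain_matches_closed_form(self):
        net = make_net([("a", "b", 0.5, 1), ("b", "c", 0.5, 1)], {"a": "TF"})
        got = influence_spread(net, ["a"], ["b", "c"], n_sim=20_000, seed=3)
        assert got == pytest.approx(0.75, abs=0.02)

    def test_time_budget_discards_late_activations(self):
        # delay 3+3 exceeds T-1=3: c unreachable within the window
        net = make_net([("a", "b", 1.0, 3), ("b", "c", 1.0, 3)], {"a": "TF"})
        assert influence_spread(net, ["a"], ["b", "c"], n_sim=10) == 1.0

    def test_monotone_in_seed_set(self):
        rng = np.random.default_rng(0)
        for trial in range(10):
            g = nx.gnp_random_graph(7, 0.35, seed=int(rng.integers(1e6)), directed=True)
            edges = [(f"n{u}", f"n{v}", float(rng.random()), int(rng.integers(0, 3)))
                     for u, v in g.edges]
            net = make_net(edges, {}, n_time=5)
            nodes = [f"n{i}" for i in range(7)]
            targets = nodes[4:]
            s1 = influence_spread(net, nodes[:1], targets, n_sim=3000, seed=trial)
            s2 = influence_spread(net, nodes[:3], targets, n_sim=3000, seed=trial)
            assert s2 >= s1 - 1e-9  # common draws: superset never loses

    def test_invalid_n_sim(self):
        net = make_net([("a", "b", 1.0, 1)], {"a": "TF"})
        with pytest.raises(ValueError, match="n_sim"):
            influence_spread(net, ["a"], ["b"], n_sim=0)


def exact_spread(net, seeds, targets):
    """Deterministic reachability spread for p in {0,1} instances."""
    g = nx.DiGraph()
    g.add_nodes_from(net.graph.nodes)
    for u, v, d in net.graph.edges(data=True):
        if d["p"] >= 1.0:
            g.add_edge(u, v, delay=d["delay"])
    count = 0
    budget = net.time_budget
    for t in targets:
        best = math.inf
        for s in seeds:
            if s == t:
                best = 0
                break
            if nx.has_path(g, s, t):
                best = min(best, nx.shortest_path_length(g, s, t, weight="delay"))
        if best <= budget:
            count += 1
    return float(count)


class TestGreedyLabeledIM:
    def test_single_tf_full_coverage(self):
        net = make_net(
            [("tf", "x", 1.0, 1), ("x", "y", 1.0, 1)],
            {"tf": "TF", "x": "pathway_gene", "y": "pathway_gene"},
        )
        result = greedy_labeled_im(net, k=1, n_sim=100, seed=0)
        assert result == [("tf", 2.0)]

    def test_disjoint_coverage_selected_in_size_order(self):
        edges = [("t1", f"a{i}", 1.0, 1) for i in range(3)]
        edges += [("t2", f"b{i}", 1.0, 1) for i in range(2)]
        labels = {"t1": "TF", "t2": "TF"}
        labels.update({f"a{i}": "pathway_gene" for i in range(3)})
        labels.update({f"b{i}": "pathway_gene" for i in range(2)})
        net = make_net(edges, labels)
        result = greedy_labeled_im(net, k=2, n_sim=100, seed=0)
        assert result == [("t1", 3.0), ("t2", 2.0)]

    def test_labeled_restriction_counts_targets_only(self):
        net = make_net(
            [("tf", "x", 1.0, 1), ("tf", "y", 1.0, 1)],
            {"tf": "TF", "x": "pathway_gene", "y": "other"},
        )
        (pair,) = greedy_labeled_im(net, k=1, n_sim=50, seed=0)
        assert pair == ("tf", 1.0)

    def test_no_reachable_target_warns_empty(self, caplog):
        net = make_net([("tf", "x", 0.0, 1)], {"tf": "TF", "x": "pathway_gene"})
        with caplog.at_level("WARNING"):
            assert greedy_labeled_im(net, k=1, n_sim=50, seed=0) == []
        assert "no TF" in caplog.text

    def test_greedy_within_constant_factor_of_optimum(self):
        """(1 - 1/e) guarantee against brute force on deterministic instances."""
        rng = np.random.default_rng(1)
        for trial in range(20):
            n = int(rng.integers(4, 9))
            g = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(1e6)), directed=True)
            edges = [(f"n{u}", f"n{v}", float(rng.integers(0, 2)), int(rng.integers(0, 2)))
                     for u, v in g.edges]
            tfs = [f"n{i}" for i in range(min(3, n))]
            targets = [f"n{i}" for i in range(n - 3, n)]
            labels = {t: "TF" for t in tfs}
            net = make_net(edges, labels, n_time=4)
            for t in targets:
                if t in net.graph:
                    net.graph.nodes[t]["label"] = "pathway_gene"
            k = 2
            result = greedy_labeled_im(net, candidate_seeds=tfs, targets=targets,
                                       k=k, n_sim=1, seed=trial)
            greedy_spread = sum(gain for _, gain in result)
            best = 0.0
            for combo in itertools.combinations(tfs, min(k, len(tfs))):
                best = max(best, exact_spread(net, combo, targets))
            assert greedy_spread >= (1 - 1 / math.e) * best - 1e-9


class TestRegulatoryPaths:
    def test_unique_path_returned_with_product_score(self):
        net = make_net(
            [("tf", "m", 0.8, 1), ("m", "P1", 0.5, 1)],
            {"tf": "TF", "m": "mediator", "P1": "pathway_gene"},
        )
        (path,) = extract_regulatory_paths(net, "tf", SUBPATHWAY, max_paths=1)
        assert path.nodes == ["tf", "m", "P1"]
        assert path.score == pytest.approx(0.4)
        assert path.cumulative_delay == 2

    def test_higher_product_ranks_first(self):
        net = make_net(
            [("tf", "a", 0.9, 1), ("a", "P1", 0.9, 1),
             ("tf", "b", 0.95, 1), ("b", "P1", 0.5, 1)],
            {"tf": "TF", "P1": "pathway_gene"},
        )
        paths = extract_regulatory_paths(net, "tf", SUBPATHWAY, max_paths=2)
        assert paths[0].nodes == ["tf", "a", "P1"]
        assert paths[0].score == pytest.approx(0.81)
        assert paths[1].score == pytest.approx(0.475)

    def test_mediator_requirement_filters_paths(self, caplog):
        net = make_net(
            [("tf", "x", 0.9, 1), ("x", "P1", 0.9, 1)],
            {"tf": "TF", "x": "other", "P1": "pathway_gene"},
        )
        with caplog.at_level("WARNING"):
            assert extract_regulatory_paths(net, "tf", SUBPATHWAY,
                                            require_mediator=True) == []
        assert "mediator" in caplog.text

    def test_delay_budget_excludes_slow_paths(self):
        net = make_net([("tf", "x", 1.0, 2), ("x", "P1", 1.0, 2)],
                       {"tf": "TF", "P1": "pathway_gene"}, n_time=4)
        assert extract_regulatory_paths(net, "tf", SUBPATHWAY) == []

    def test_non_tf_source_rejected(self):
        net = make_net([("a", "P1", 1.0, 1)], {"a": "other", "P1": "pathway_gene"})
        with pytest.raises(ValueError, match="TF"):
            extract_regulatory_paths(net, "a", SUBPATHWAY)

    def test_agrees_with_brute_force_enumeration(self):
        rng = np.random.default_rng(2)
        for trial in range(30):
            n = int(rng.integers(5, 11))
            g = nx.gnp_random_graph(n, 0.35, seed=int(rng.integers(1e6)), directed=True)
            edges = [(f"n{u}", f"n{v}", float(rng.uniform(0.1, 1.0)),
                      int(rng.integers(0, 2))) for u, v in g.edges]
            net = make_net(edges, {"n0": "TF"}, n_time=6)
            targets = [f"n{i}" for i in range(n - 2, n)]
            sp = PerturbedSubpathway(
                "pw", 0,
                [EdgeValidation((targets[0], targets[1]), 1, 1, True)], 1.0,
            )
            got = extract_regulatory_paths(net, "n0", sp, max_paths=5)
            expected = brute_force_paths(net, "n0", set(targets), max_paths=5)
            assert [(p.nodes, round(p.score, 12)) for p in got] == [
                (nodes, round(score, 12)) for nodes, score in expected
            ]

    def test_emitted_paths_satisfy_invariants(self):
        net = make_net(
            [("tf", "a", 0.5, 1), ("a", "P1", 0.5, 1), ("a", "P2", 0.9, 2)],
            {"tf": "TF", "P1": "pathway_gene", "P2": "pathway_gene"},
        )
        for p in extract_regulatory_paths(net, "tf", SUBPATHWAY, max_paths=10):
            assert net.graph.nodes[p.nodes[0]]["label"] == "TF"
            for u, v in zip(p.nodes, p.nodes[1:]):
                assert net.graph.has_edge(u, v)
            assert p.cumulative_delay <= net.time_budget


def brute_force_paths(net, tf, targets, max_paths):
    """Exhaustive simple-path enumeration with the same ranking key."""
    g = net.graph
    found = []
    for t in targets:
        if t not in g or t == tf:
            continue
        for nodes in nx.all_simple_paths(g, tf, t):
            delay = sum(g.edges[u, v]["delay"] for u, v in zip(nodes, nodes[1:]))
            if delay > net.time_budget:
                continue
            score = 1.0
            for u, v in zip(nodes, nodes[1:]):
                score *= g.edges[u, v]["p"]
            found.append((list(nodes), score))
    found.sort(key=lambda ns: (-ns[1], len(ns[0]), ns[0]))
    return found[:max_paths]


class TestTerminators:
    def test_chain_tail(self):
        net = make_net([("a", "b", 1.0, 1), ("b", "c", 1.0, 1)], {})
        assert terminator_proteins(net) == {"c"}

    def test_cycle_has_none(self):
        net = make_net([("a", "b", 1.0, 1), ("b", "a", 1.0, 1)], {})
        assert terminator_proteins(net) == set()

    def test_isolated_node_included(self):
        net = make_net([("a", "b", 1.0, 1)], {})
        net.graph.add_node("lonely", label="other")
        assert terminator_proteins(net) == {"b", "lonely"}
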