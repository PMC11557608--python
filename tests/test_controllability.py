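from fractions import Fraction

import networkx as nx
import numpy as np
import pytest

from uprnet.controllability import (
    ControlSystem,
    build_system,
    enumerate_driver_sets,
    kalman_controllable,
    minimum_driver_nodes,
    verify_driver_set,
)
from uprnet.synthetic import canonical_graph

from conftest import brute_min_driver_count


def _sys(A_rows, B_rows, nodes, inputs):
    A = [[Fraction(x) for x in row] for row in A_rows]
    B = [[Fraction(x) for x in row] for row in B_rows]
    return ControlSystem(A=A, B=B, nodes=nodes, input_nodes=inputs)


class TestBuildSystem:
    def test_path_with_single_input(self):
        g = nx.Graph([("a", "b"), ("b", "c")])
        sys = build_system(g, ["a"])
        nz = {(i, j) for i in range(3) for j in range(3) if sys.A[i][j] != 0}
        assert nz == {(0, 1), (1, 0), (1, 2), (2, 1)}  # symmetric ab/bc pattern
        assert [row[0] for row in sys.B] == [Fraction(1), Fraction(0), Fraction(0)]

    def test_all_nodes_as_inputs_gives_identity_selection(self):
        g = nx.Graph([("a", "b")])
        sys = build_system(g, ["a", "b"])
        assert sys.B == [[1, 0], [0, 1]]

    def test_duplicate_input_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_system(nx.Graph([("a", "b")]), ["a", "a"])

    def test_generic_weights_are_seeded_and_bounded(self):
        g = canonical_graph("cycle", 5)
        s1 = build_system(g, ["v1"], weight_mode="generic", seed=3)
        s2 = build_system(g, ["v1"], weight_mode="generic", seed=3)
        assert s1.A == s2.A
        vals = [abs(x) for row in s1.A for x in row if x != 0]
        assert all(Fraction(1, 2) <= v <= Fraction(3, 2) for v in vals)


class TestKalman:
    def test_directed_chain_controllable_from_source(self):
        sys = _sys([[0, 0], [1, 0]], [[1], [0]], [1, 2], [1])
        assert kalman_controllable(sys)

    def test_directed_chain_not_controllable_from_sink(self):
        sys = _sys([[0, 0], [1, 0]], [[0], [1]], [1, 2], [2])
        assert not kalman_controllable(sys)

    def test_isolated_nodes_need_individual_inputs(self):
        sys = _sys([[0] * 3 for _ in range(3)], [[1], [0], [0]], [1, 2, 3], [1])
        assert not kalman_controllable(sys)

    def test_exact_and_numeric_paths_agree_on_small_systems(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            g = nx.gnp_random_graph(6, 0.4, seed=int(rng.integers(2**31)))
            sys = build_system(g, [0, 3], weight_mode="generic", seed=1)
            assert kalman_controllable(sys, rank_exact_cutoff=12) == \
                kalman_controllable(sys, rank_exact_cutoff=0)


class TestMinimumDrivers:
    def test_three_isolated_nodes(self):
        g = nx.empty_graph(3)
        assert minimum_driver_nodes(g, verify=False).driver_count == 3

    def test_undirected_star_needs_two(self):
        res = minimum_driver_nodes(canonical_graph("star", 4))
        assert res.driver_count == 2
        assert res.verified is True

    def test_directed_path_single_source_driver(self):
        res = minimum_driver_nodes(nx.DiGraph([(1, 2), (2, 3)]))
        assert res.driver_count == 1
        assert res.driver_sets == [frozenset({1})]

    def test_disjoint_edges_need_one_driver_each(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        assert minimum_driver_nodes(g).driver_count == 2

    def test_inaccessible_cycle_needs_extra_driver(self):
        # two 2-cycles feeding a sink: one unmatched node cannot reach both
        d = nx.DiGraph([(1, 2), (2, 1), (3, 4), (4, 3), (2, 5), (4, 5)])
        res = minimum_driver_nodes(d)
        assert res.driver_count == 2
        assert res.verified is True

    def test_invariant_under_relabeling(self):
        g = nx.gnp_random_graph(7, 0.3, seed=4)
        relabeled = nx.relabel_nodes(g, {i: f"P{i}" for i in g.nodes()})
        assert (minimum_driver_nodes(g, verify=False).driver_count
                == minimum_driver_nodes(relabeled, verify=False).driver_count)

    def test_matches_bruteforce_on_spot_checks(self, graph_corpus):
        for g in graph_corpus[:10]:
            assert (minimum_driver_nodes(g, verify=False).driver_count
                    == brute_min_driver_count(g))


class TestEnumeration:
    def test_directed_path_has_unique_set(self):
        res = enumerate_driver_sets(nx.DiGraph([(1, 2), (2, 3)]))
        assert res.driver_sets == [frozenset({1})]

    def test_single_edge_both_endpoints_work(self):
        res = enumerate_driver_sets(nx.Graph([("a", "b")]))
        assert set(res.driver_sets) == {frozenset({"a"}), frozenset({"b"})}

    def test_two_isolated_nodes_single_set(self):
        g = nx.empty_graph(2)
        res = enumerate_driver_sets(g)
        assert res.driver_sets == [frozenset({0, 1})]

    def test_star_leaf_pairs(self):
        res = enumerate_driver_sets(canonical_graph("star", 4))
        assert set(res.driver_sets) == {
            frozenset({"v2", "v3"}), frozenset({"v2", "v4"}), frozenset({"v3", "v4"})
        }

    def test_cap_truncates_with_flag(self):
        res = enumerate_driver_sets(canonical_graph("complete", 6), cap=3)
        assert len(res.driver_sets) == 3 and res.truncated

    def test_cap_must_be_positive(self):
        with pytest.raises(ValueError):
            enumerate_driver_sets(nx.Graph([("a", "b")]), cap=0)

    def test_every_enumerated_set_is_kalman_verified(self, graph_corpus):
        for g in graph_corpus[:8]:
            res = enumerate_driver_sets(g, cap=16)
            for s in res.driver_sets:
                assert verify_driver_set(g, s, seed=1)


class TestVerification:
    def test_full_node_set_always_controllable(self):
        g = canonical_graph("two_clique_bridge", 6)
        assert verify_driver_set(g, list(g.nodes()))

    def test_single_driver_fails_on_edgeless_pair(self):
        assert not verify_driver_set(nx.empty_graph(2), [0])

    def test_empty_candidate_rejected(self):
        assert not verify_driver_set(nx.Graph([("a", "b")]), [])
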