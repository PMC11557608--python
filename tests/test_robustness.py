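import networkx as nx
import numpy as np
import pytest

from uprnet.robustness import attack_order, detect_jumps, robustness_R, run_attack
from uprnet.synthetic import canonical_graph


def lcc_sizes_bruteforce(net, order):
    """Independent recomputation: full component scan by hand after each removal."""
    g = net.copy()
    sizes = []
    for v in order:
        g.remove_node(v)
        remaining = set(g.nodes())
        best = 0
        while remaining:
            stack = [remaining.pop()]
            comp = 1
            while stack:
                u = stack.pop()
                for w in list(g.neighbors(u)):
                    if w in remaining:
                        remaining.discard(w)
                        stack.append(w)
                        comp += 1
            best = max(best, comp)
        sizes.append(best)
    return sizes


class TestAttackOrder:
    def test_star_degree_descending_removes_center_first(self):
        order = attack_order(canonical_graph("star", 5), "degree", "descending")
        assert order[0] == "v1"

    def test_star_degree_ascending_removes_center_last(self):
        order = attack_order(canonical_graph("star", 5), "degree", "ascending")
        assert order[-1] == "v1"

    def test_path_betweenness_descending_targets_midpoint(self):
        order = attack_order(canonical_graph("path", 3), "betweenness", "descending")
        assert order[0] == "v2"

    def test_random_is_seeded_permutation(self):
        g = canonical_graph("cycle", 8)
        a = attack_order(g, "random", seed=5)
        b = attack_order(g, "random", seed=5)
        c = attack_order(g, "random", seed=6)
        assert a == b and sorted(a) == sorted(g.nodes())
        assert a != c

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError):
            attack_order(canonical_graph("star", 4), "pagerank")


class TestTraces:
    def test_complete_graph_degrades_linearly(self):
        g = canonical_graph("complete", 10)
        trace = run_attack(g, sorted(g.nodes(), key=str))
        assert trace.lcc_fraction == pytest.approx([(10 - i) / 10 for i in range(1, 11)])
        assert robustness_R(trace) == pytest.approx(0.45)

    def test_star_center_first_trace(self):
        trace = run_attack(canonical_graph("star", 5), ["v1", "v2", "v3", "v4", "v5"])
        assert trace.lcc_fraction == pytest.approx([0.2, 0.2, 0.2, 0.2, 0.0])
        assert robustness_R(trace) == pytest.approx(0.16)

    def test_star_leaves_first_trace(self):
        trace = run_attack(canonical_graph("star", 5), ["v2", "v3", "v4", "v5", "v1"])
        assert trace.lcc_fraction == pytest.approx([0.8, 0.6, 0.4, 0.2, 0.0])
        assert robustness_R(trace) == pytest.approx(0.40)

    def test_non_permutation_rejected(self):
        g = canonical_graph("path", 3)
        with pytest.raises(ValueError):
            run_attack(g, ["v1", "v1", "v2"])

    def test_efficiency_drop_monotone_and_bounded(self):
        g = canonical_graph("two_clique_bridge", 10)
        for strat in ("degree", "betweenness"):
            trace = run_attack(g, attack_order(g, strat, "descending"))
            drops = trace.efficiency_drop
            assert all(0 <= d <= 1 + 1e-12 for d in drops)
            assert all(b >= a - 1e-12 for a, b in zip(drops, drops[1:]))
            assert drops[-1] == pytest.approx(1.0)

    def test_agrees_with_bruteforce_component_scan(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            g = nx.gnp_random_graph(12, 0.25, seed=int(rng.integers(2**31)))
            order = attack_order(g, "random", seed=int(rng.integers(2**31)))
            trace = run_attack(g, order, efficiency=False)
            assert trace.lcc_sizes == lcc_sizes_bruteforce(g, order)


class TestJumps:
    def test_star_center_removal_flagged(self):
        trace = run_attack(canonical_graph("star", 5), ["v1", "v2", "v3", "v4", "v5"])
        jumps = detect_jumps(trace, 0.10)
        assert jumps[0][:2] == (1, "v1")
        assert jumps[0][2] == pytest.approx(0.8)

    def test_inclusive_boundary_on_complete_graph(self):
        g = canonical_graph("complete", 10)
        trace = run_attack(g, sorted(g.nodes(), key=str), efficiency=False)
        # each removal drops the LCC by exactly 10% of N: inclusive flags all
        assert len(detect_jumps(trace, 0.10)) == 10
        assert len(detect_jumps(trace, 0.10, strict=True)) == 0

    def test_path_bridge_removal(self):
        trace = run_attack(canonical_graph("path", 3), ["v2", "v1", "v3"])
        jumps = detect_jumps(trace, 0.10)
        assert jumps[0][0] == 1
        assert jumps[0][2] == pytest.approx(1 - 1 / 3)

    def test_hub_first_attack_weaker_than_hub_last(self):
        for g in (canonical_graph("star", 9),
                  nx.barabasi_albert_graph(30, 1, seed=2)):
            desc = run_attack(g, attack_order(g, "degree", "descending"), efficiency=False)
            asc = run_attack(g, attack_order(g, "degree", "ascending"), efficiency=False)
            assert robustness_R(desc) <= robustness_R(asc)


def test_lcc_fraction_never_increases_across_strategies():
    rng = np.random.default_rng(3)
    for _ in range(10):
        g = nx.gnp_random_graph(14, 0.2, seed=int(rng.integers(2**31)))
        for strat in ("random", "degree", "closeness", "betweenness"):
            order = attack_order(g, strat, "ascending", seed=7)
            trace = run_attack(g, order, efficiency=False)
            seq = [trace.initial_lcc_size] + trace.lcc_sizes
            assert all(b <= a for a, b in zip(seq, seq[1:]))
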