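import itertools

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from uprnet.null_models import (
    build_ensemble,
    configuration_model,
    cross_species_test,
    ensemble_zscores,
    hierarchical_dendrogram,
    paired_signed_rank,
    pearson,
    zscore,
)
from uprnet.organisms import organism_table
from uprnet.synthetic import canonical_graph


def signed_rank_enumeration(diffs):
    """Independent oracle: exact two-sided p by enumerating all 2^n sign
    assignments of the tie-averaged ranks."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=len(d))
    ]
    ws = np.array(ws)
    cdf = np.mean(ws <= w_obs + 1e-12)
    sf = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2 * min(cdf, sf))


class TestConfigurationModel:
    def test_star_sequence_returns_star(self):
        g = configuration_model(canonical_graph("star", 4), seed=3)
        degs = sorted(d for _, d in g.degree())
        assert degs == [1, 1, 1, 3]
        assert g.number_of_edges() == 3

    @pytest.mark.parametrize("kind,n", [("cycle", 6), ("two_clique_bridge", 10), ("star", 8)])
    def test_degree_sequence_preserved_exactly(self, kind, n):
        native = canonical_graph(kind, n)
        for seed in range(10):
            rep = configuration_model(native, seed=seed)
            assert dict(rep.degree()) == dict(native.degree())
            assert all(a != b for a, b in rep.edges())

    def test_six_cycle_randomization_varies_across_seeds(self):
        native = canonical_graph("cycle", 6)
        edge_sets = {
            frozenset(map(frozenset, configuration_model(native, seed=s).edges()))
            for s in range(10)
        }
        assert len(edge_sets) > 1

    def test_same_seed_reproducible(self):
        native = canonical_graph("two_clique_bridge", 12)
        a = configuration_model(native, seed=5)
        b = configuration_model(native, seed=5)
        assert set(a.edges()) == set(b.edges())


class TestZScores:
    def test_sample_sd_arithmetic(self):
        z = zscore(10, [2, 4, 6])
        assert z.value == pytest.approx(3.0)

    def test_native_at_mean_is_zero(self):
        assert zscore(4.0, [2, 4, 6]).value == pytest.approx(0.0)

    def test_zero_spread_flagged_undefined(self):
        z = zscore(1.0, [5, 5, 5])
        assert z.value is None and not z.defined

    def test_ensemble_zscores_on_fixture(self):
        g = canonical_graph("two_clique_bridge", 10)
        zs = ensemble_zscores(g, R=5, seed=1)
        assert set(zs) == {"closeness", "betweenness", "clustering"}
        # randomization destroys the two-clique clustering: native must sit
        # above the ensemble mean
        assert zs["clustering"].native >= zs["clustering"].mean

    def test_requires_two_replicates(self):
        with pytest.raises(ValueError):
            ensemble_zscores(canonical_graph("cycle", 5), R=1)


class TestSignedRank:
    def test_identical_pairs_give_one_with_warning(self):
        with pytest.warns(UserWarning):
            assert paired_signed_rank([1, 2, 3], [1, 2, 3]) == 1.0

    def test_five_positive_differences_exact(self):
        assert paired_signed_rank([1, 2, 3, 4, 5], [0, 0, 0, 0, 0]) == pytest.approx(2 / 32)

    def test_antisymmetric_differences(self):
        assert paired_signed_rank([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_matches_sign_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for n in range(3, 11):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            assert paired_signed_rank(x, y) == pytest.approx(
                signed_rank_enumeration(x - y), abs=1e-12
            )


class TestCrossSpecies:
    def test_identical_groups_capped_at_one(self):
        m = cross_species_test([[1, 2, 3, 4, 5], [1, 2, 3, 4, 5]])
        assert m[0, 1] == 1.0 and np.isnan(m[0, 0])

    def test_fully_separated_groups(self):
        m = cross_species_test([[1, 2, 3, 4, 5], [101, 102, 103, 104, 105]])
        # exact KW H for complete separation at n1=n2=5 is 6.82
        expected = stats.chi2.sf(6.8181818, 1)
        assert m[0, 1] == pytest.approx(expected, rel=1e-5)
        assert m[0, 1] < 0.05

    def test_only_shifted_pairs_significant(self):
        a = [1.0, 1.5, 2.0, 2.5, 3.0, 3.5]
        b = [1.1, 1.4, 2.1, 2.4, 3.1, 3.4]
        c = [x + 100 for x in a]
        m = cross_species_test([a, b, c])
        assert m[0, 2] < 0.05 and m[1, 2] < 0.05
        assert m[0, 1] > 0.5

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            cross_species_test([[1, 2, 3], [4]])


class TestPearson:
    def test_reference_column_pairs(self):
        df = organism_table()
        r_cb, p_cb = pearson(df["avg_closeness"], df["avg_betweenness"])
        r_dc, _ = pearson(df["avg_degree"], df["avg_closeness"])
        r_db, _ = pearson(df["avg_degree"], df["avg_betweenness"])
        assert round(r_cb, 2) == -0.94
        assert p_cb == pytest.approx(4e-6, rel=0.2)
        assert round(r_dc, 2) == -0.04
        assert round(r_db, 3) == 0.006

    def test_perfect_line(self):
        r, p = pearson([1, 2, 3, 4], [3, 5, 7, 9])
        assert r == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        assert pearson([1, 1, 1], [1, 2, 3]) == (None, None)


class TestDendrogram:
    def test_closest_scalars_merge_first(self):
        link = hierarchical_dendrogram([[0.0], [0.1], [5.0]])
        assert sorted(link[0, :2]) == [0, 1]

    def test_identical_vectors_merge_at_zero(self):
        link = hierarchical_dendrogram([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]])
        assert link[0, 2] == pytest.approx(0.0)

    def test_upgma_height_hand_computed(self):
        link = hierarchical_dendrogram([[0.0], [1.0], [2.5]])
        assert link[0, 2] == pytest.approx(1.0)
        assert link[1, 2] == pytest.approx(2.0)  # mean of 2.5 and 1.5


def test_build_ensemble_tables_are_normalized():
    ens = build_ensemble(canonical_graph("two_clique_bridge", 10), R=3, seed=0)
    assert ens.R == 3
    for t in ens.tables:
        assert "norm_closeness" in t.nodes.columns
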