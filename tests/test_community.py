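import math

import networkx as nx
import numpy as np
import pytest

from feednet import (
    bray_curtis_similarity,
    community_network,
    degree_preserving_rewire,
    filter_edges,
    network_permutation_test,
    pairwise_species_similarity,
    simulate_abundance,
)
from feednet.community import STATISTICS, SimilarityMatrix


def bc_oracle(x, y):
    """Bray-Curtis similarity straight from the formula."""
    num = sum(abs(a - b) for a, b in zip(x, y))
    den = sum(a + b for a, b in zip(x, y))
    return 1.0 - num / den


class TestBrayCurtis:
    def test_identical_vectors(self):
        assert bray_curtis_similarity([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_disjoint_supports(self):
        assert bray_curtis_similarity([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_hand_example(self):
        assert bray_curtis_similarity([1, 2, 3], [3, 2, 1]) == pytest.approx(2.0 / 3)

    def test_symmetry_and_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            x = rng.random(8) * rng.integers(1, 100)
            y = rng.random(8) * rng.integers(1, 100)
            s = bray_curtis_similarity(x, y)
            assert s == pytest.approx(bray_curtis_similarity(y, x), abs=1e-12)
            assert s == pytest.approx(bc_oracle(x, y), abs=1e-12)

    def test_not_scale_invariant(self):
        # similarity depends on absolute abundances, not just profiles
        x, y = np.array([1.0, 2.0]), np.array([2.0, 4.0])
        assert bray_curtis_similarity(x, y) != pytest.approx(1.0)

    def test_both_zero_undefined(self):
        assert math.isnan(bray_curtis_similarity([0, 0], [0, 0]))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis_similarity([-1, 1], [1, 1])


class TestPairwiseSimilarity:
    def test_symmetric_unit_diagonal(self, study):
        sim = pairwise_species_similarity(study.abundance, "BF", n_boot=20, seed=0)
        present = ~np.isnan(sim.similarity)
        np.testing.assert_allclose(
            sim.similarity[present], sim.similarity.T[present], atol=1e-12
        )
        diag = np.diag(sim.similarity)
        np.testing.assert_allclose(diag[~np.isnan(diag)], 1.0)

    def test_matches_direct_formula_per_pair(self, small_abundance):
        sim = pairwise_species_similarity(small_abundance, "BF", n_boot=5, seed=0)
        sub = small_abundance.subset_group("BF")
        for i in range(3):
            for j in range(3):
                assert sim.similarity[i, j] == pytest.approx(
                    bc_oracle(sub.values[i], sub.values[j]), abs=1e-12
                )

    def test_absent_species_isolated(self, small_abundance):
        small_abundance.values[2, :2] = 0.0  # spC absent in BF
        net = community_network(small_abundance, "BF", n_boot=20, seed=0)
        assert net.degree["spC"] == 0
        assert "spC" in net.nodes

    def test_single_bootstrap_flags_unstable(self, small_abundance, caplog):
        with caplog.at_level("WARNING"):
            sim = pairwise_species_similarity(small_abundance, "BF", n_boot=1, seed=0)
        assert np.isinf(sim.boot_sd[0, 1])


class TestFilterEdges:
    def _sim(self, mean, sd):
        ids = ["a", "b"]
        m = np.array([[1.0, mean], [mean, 1.0]])
        s = np.array([[0.0, sd], [sd, 0.0]])
        return SimilarityMatrix(ids, m, m, s, n_boot=10)

    def test_zero_sd_positive_mean_kept(self):
        assert filter_edges(self._sim(0.5, 0.0)) == [("a", "b", 0.5)]

    def test_zero_mean_dropped(self):
        assert filter_edges(self._sim(0.0, 0.0)) == []

    def test_unstable_pair_dropped(self):
        assert filter_edges(self._sim(0.4, 0.3), k=2.0) == []

    def test_output_subset_of_positive_mean_pairs(self, study):
        sim = pairwise_species_similarity(study.abundance, "FF", n_boot=30, seed=1)
        ids = {f: i for i, f in enumerate(sim.feature_ids)}
        for u, v, _ in filter_edges(sim):
            assert sim.boot_mean[ids[u], ids[v]] > 0

    def test_planted_proportional_pair_kept_noise_dropped(self):
        # two species sharing a profile survive the stability filter while
        # an independent sparse pair does not, across seeds
        kept = dropped = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            profile = rng.random(6) * 10 + 5
            values = np.vstack(
                [
                    profile,
                    profile * 1.1 + rng.normal(0, 0.2, 6),
                    rng.random(6) * (rng.random(6) > 0.7),
                    rng.random(6) * (rng.random(6) > 0.7),
                ]
            )
            from feednet.data_io import AbundanceTable

            t = AbundanceTable(
                species_ids=["p1", "p2", "q1", "q2"],
                sample_ids=[f"s{i}" for i in range(6)],
                group=["BF"] * 6,
                values=values,
            )
            sim = pairwise_species_similarity(t, "BF", n_boot=100, seed=seed)
            edges = {(u, v) for u, v, _ in filter_edges(sim)}
            kept += ("p1", "p2") in edges
            dropped += ("q1", "q2") not in edges
        assert kept >= 18
        assert dropped >= 18


class TestRewiring:
    def test_triangle_returned_isomorphic(self):
        k3 = nx.complete_graph(3)
        out = degree_preserving_rewire(k3, seed=0)
        assert nx.is_isomorphic(out, k3)

    def test_degree_sequence_preserved_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            g = nx.gnp_random_graph(12, 0.3, seed=int(rng.integers(2**31)))
            out = degree_preserving_rewire(g, seed=int(rng.integers(2**31)))
            assert sorted(d for _, d in out.degree) == sorted(d for _, d in g.degree)
            assert out.number_of_edges() == g.number_of_edges()
            assert set(out.nodes) == set(g.nodes)

    def test_p4_reaches_both_realizations(self):
        # degree sequence (1,1,2,2) has two labelled realizations reachable
        # by swaps: the path and a triangle-free alternative pairing
        p4 = nx.path_graph(4)
        seen = set()
        for seed in range(200):
            out = degree_preserving_rewire(p4, seed=seed)
            seen.add(frozenset(map(frozenset, out.edges)))
        assert len(seen) >= 2

    def test_fewer_than_two_edges_unchanged(self, caplog):
        g = nx.Graph([("a", "b")])
        with caplog.at_level("WARNING"):
            out = degree_preserving_rewire(g, seed=0)
        assert set(out.edges) == {("a", "b")}


class TestPermutationTest:
    @staticmethod
    def _first_call_statistic(observed_value, null_value):
        # the observed graph is evaluated once, before any null draw
        calls = {"n": 0}

        def stat(_g):
            calls["n"] += 1
            return observed_value if calls["n"] == 1 else null_value

        return stat

    def test_observed_below_all_nulls(self):
        STATISTICS["_low"] = self._first_call_statistic(-1.0, 0.0)
        try:
            g = nx.gnp_random_graph(10, 0.4, seed=1)
            res = network_permutation_test(g, "_low", n_permutations=50, seed=0)
            assert res.p_empirical == pytest.approx(1.0)
        finally:
            del STATISTICS["_low"]

    def test_observed_above_all_nulls_hits_lower_bound(self):
        STATISTICS["_high"] = self._first_call_statistic(1.0, 0.0)
        try:
            g = nx.gnp_random_graph(10, 0.4, seed=1)
            res = network_permutation_test(g, "_high", n_permutations=1000, seed=0)
            assert res.p_empirical == pytest.approx(1.0 / 1001)
        finally:
            del STATISTICS["_high"]

    def test_constant_null_gives_nan_zscore(self):
        g = nx.complete_graph(3)  # unique realization: null is constant
        res = network_permutation_test(g, "edge_count", n_permutations=20, seed=0)
        assert math.isnan(res.p_zscore)
        assert 0 < res.p_empirical <= 1

    def test_report_is_jsonable(self):
        g = nx.gnp_random_graph(10, 0.4, seed=2)
        res = network_permutation_test(g, "clustering", n_permutations=30, seed=0)
        d = res.to_jsonable()
        assert d["n_permutations"] == 30
        assert 0 < d["p_empirical"] <= 1

    def test_unknown_statistic_rejected(self):
        with pytest.raises(ValueError):
            network_permutation_test(nx.path_graph(3), "betweenness")


class TestCommunityNetworkEndToEnd:
    def test_all_species_present_as_nodes(self, study):
        net = community_network(study.abundance, "BF", n_boot=30, seed=0)
        assert set(net.nodes) == set(study.abundance.species_ids)
        for _, _, d in net.edges(data=True):
            assert d["edge_type"] == "co_abundance"
            assert 0 < d["weight"] <= 1
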