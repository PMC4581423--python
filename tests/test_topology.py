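import math

import networkx as nx
import numpy as np
import pytest

from feednet import (
    diameter,
    largest_component_size,
    merge_layers,
    reachability_profile,
    shortest_path_distribution,
    topology_report,
)


def floyd_warshall_diameter(g):
    """Brute-force diameter of the largest component via Floyd-Warshall."""
    nodes = list(max(nx.connected_components(g), key=len))
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for u, v in g.edges:
        if u in idx and v in idx:
            d[idx[u], idx[v]] = d[idx[v], idx[u]] = 1.0
    for k in range(n):
        d = np.minimum(d, d[:, k : k + 1] + d[k : k + 1, :])
    return float(d.max())


def _typed(g, node_type="species", edge_type="co_abundance"):
    nx.set_node_attributes(g, node_type, "node_type")
    nx.set_edge_attributes(g, edge_type, "edge_type")
    return g


class TestMergeLayers:
    def _layers(self):
        coexpr = _typed(nx.path_graph(["g1", "g2", "g3"]), "de_gene", "co_expression")
        community = _typed(nx.path_graph(["s1", "s2"]))
        return coexpr, community

    def test_empty_relations_layers_stay_disconnected(self):
        coexpr, community = self._layers()
        merged = merge_layers(coexpr, community, [], de_genes={"g1", "g2", "g3"})
        assert nx.number_connected_components(merged) == 2

    def test_one_relation_bridges_layers(self):
        coexpr, community = self._layers()
        merged = merge_layers(
            coexpr, community, [("s1", "g1", "de_gene")], de_genes={"g1", "g2", "g3"}
        )
        assert nx.number_connected_components(merged) == 1
        assert merged.edges["s1", "g1"]["edge_type"] == "literature_relation"

    def test_type_counts_conserved(self, study):
        from feednet import accept_relations, coexpression_network, community_network

        coexpr = coexpression_network(study.expression, "BF")
        community = community_network(study.abundance, "BF", n_boot=30, seed=0)
        rel = accept_relations(study.counts, de_genes=study.truth.de_genes)
        edges = [(r.species, r.gene, r.gene_type) for r in rel[rel.accepted].itertuples()]
        merged = merge_layers(coexpr, community, edges, de_genes=study.truth.de_genes)
        types = {t: 0 for t in ("species", "de_gene", "transient_gene")}
        for _, d in merged.nodes(data=True):
            types[d["node_type"]] += 1
        extra_genes = {g for _, g, _ in edges} - set(coexpr.nodes)
        assert types["species"] == community.number_of_nodes()
        assert types["de_gene"] + types["transient_gene"] == (
            coexpr.number_of_nodes() + len(extra_genes)
        )
        by_type = {}
        for _, _, d in merged.edges(data=True):
            by_type[d["edge_type"]] = by_type.get(d["edge_type"], 0) + 1
        assert by_type.get("co_abundance", 0) == community.number_of_edges()
        assert by_type.get("co_expression", 0) == coexpr.number_of_edges()
        assert by_type.get("literature_relation", 0) == len({(s, g) for s, g, _ in edges})

    def test_transient_gene_typing(self):
        coexpr, community = self._layers()
        merged = merge_layers(
            coexpr, community, [("s2", "g9", "transient_gene")], de_genes={"g1", "g2", "g3"}
        )
        assert merged.nodes["g9"]["node_type"] == "transient_gene"

    def test_id_collision_rejected(self):
        coexpr = _typed(nx.path_graph(["x", "g2"]), "de_gene", "co_expression")
        community = _typed(nx.path_graph(["x", "s2"]))
        with pytest.raises(ValueError, match="collision"):
            merge_layers(coexpr, community, [], de_genes=set())
        merged = merge_layers(
            coexpr, community, [], de_genes=set(), species_prefix="sp:", gene_prefix="g:"
        )
        assert {"sp:x", "g:x"} <= set(merged.nodes)


class TestPathDistributionAndDiameter:
    def test_p5_hand_bfs(self, path_graph_p5):
        assert shortest_path_distribution(path_graph_p5) == {1: 4, 2: 3, 3: 2, 4: 1}
        assert diameter(path_graph_p5) == 4

    def test_complete_graph(self):
        assert diameter(nx.complete_graph(4)) == 1

    def test_two_disjoint_edges_lcc_convention(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        assert diameter(g) == 1

    def test_edgeless_graph_missing(self):
        assert math.isnan(diameter(nx.empty_graph(3)))

    def test_histogram_counts_connected_pairs(self, path_graph_p5):
        hist = shortest_path_distribution(path_graph_p5)
        assert sum(hist.values()) == 5 * 4 // 2

    def test_matches_floyd_warshall_on_random_graphs(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            g = nx.gnp_random_graph(int(rng.integers(5, 31)), 0.2, seed=int(rng.integers(2**31)))
            if g.number_of_edges() == 0:
                continue
            assert diameter(g) == floyd_warshall_diameter(g)

    def test_adding_edge_never_lengthens_paths(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            g = nx.gnp_random_graph(12, 0.25, seed=int(rng.integers(2**31)))
            before = dict(nx.all_pairs_shortest_path_length(g))
            non_edges = list(nx.non_edges(g))
            if not non_edges:
                continue
            u, v = non_edges[int(rng.integers(len(non_edges)))]
            g.add_edge(u, v)
            after = dict(nx.all_pairs_shortest_path_length(g))
            for s, dists in before.items():
                for t, d in dists.items():
                    assert after[s][t] <= d


class TestReachability:
    def test_star_from_leaf(self):
        g = _typed(nx.star_graph(4))
        prof = reachability_profile(g, lengths=(1, 2), start_nodes=[1])
        assert prof[1]["species"] == 1
        assert prof[2]["species"] == 4

    def test_isolated_start_zero(self):
        g = _typed(nx.empty_graph(3))
        prof = reachability_profile(g, lengths=(1, 2, 3), start_nodes=[0])
        assert all(v == 0 for by in prof.values() for v in by.values())

    def test_monotone_in_length(self, study):
        from feednet import community_network

        g = community_network(study.abundance, "FF", n_boot=30, seed=0)
        prof = reachability_profile(g, lengths=(1, 2, 3))
        for t in prof[1]:
            assert prof[1][t] <= prof[2][t] <= prof[3][t]

    def test_large_length_reaches_whole_component(self):
        g = _typed(nx.path_graph(6))
        prof = reachability_profile(g, lengths=(10,), start_nodes=list(g.nodes))
        assert prof[10]["species"] == pytest.approx(5.0)

    def test_sampled_starts_reproducible(self):
        g = _typed(nx.path_graph(8))
        a = reachability_profile(g, n_starts=3, seed=5)
        b = reachability_profile(g, n_starts=3, seed=5)
        assert a == b

    def test_empty_start_set_rejected(self):
        with pytest.raises(ValueError):
            reachability_profile(_typed(nx.path_graph(3)), start_nodes=[])


class TestComponentsAndReport:
    def test_connected_graph_full_size(self):
        assert largest_component_size(nx.path_graph(7)) == 7

    def test_isolated_nodes_only(self):
        assert largest_component_size(nx.empty_graph(4)) == 1

    def test_two_components(self):
        g = nx.union(nx.complete_graph(3), nx.path_graph(5), rename=("a", "b"))
        assert largest_component_size(g) == 5

    def test_report_fields(self, path_graph_p5):
        rep = topology_report(path_graph_p5)
        assert rep.diameter == 4
        assert rep.largest_component == 5
        assert rep.n_nodes_by_type == {"species": 5}
        assert rep.n_edges_by_type == {"co_abundance": 4}
        d = rep.to_jsonable()
        assert d["path_length_histogram"] == {"1": 4, "2": 3, "3": 2, "4": 1}
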