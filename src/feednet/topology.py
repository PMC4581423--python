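"""Multi-layer host-gene-microbe network assembly and topology read-outs.

The gene co-expression layer, the species co-abundance layer and the
literature relation edges merge into one typed graph per feeding
condition.  Topology summaries — shortest-path-length distribution,
diameter (on the largest connected component), reachability by node type
— characterize how tightly the host and microbial layers are knit
together under each feeding mode.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np


def merge_layers(
    coexpr: nx.Graph,
    community: nx.Graph,
    relations: list[tuple[str, str, str]],
    de_genes: set[str],
    species_prefix: str = "",
    gene_prefix: str = "",
) -> nx.Graph:
    """Union the three layers into one typed graph.

    ``relations`` holds (species, gene, gene_type) triples.  Node types:
    community nodes are species; gene nodes are de_gene when in
    ``de_genes`` and transient_gene otherwise (genes that enter only via
    the literature layer).  Optional prefixes namespace the two id
    spaces; any id appearing in both spaces after prefixing is an error.
    """
    species_ids = {species_prefix + n for n in community.nodes}
    gene_ids = {gene_prefix + n for n in coexpr.nodes}
    gene_ids |= {gene_prefix + g for _, g, _ in relations}
    clash = species_ids & gene_ids
    if clash:
        raise ValueError(
            f"id collision between species and gene namespaces: {sorted(clash)[:5]}; "
            "set species_prefix/gene_prefix to disambiguate"
        )

    def gene_type(g: str) -> str:
        return "de_gene" if g in de_genes else "transient_gene"

    merged = nx.Graph()
    for n in community.nodes:
        merged.add_node(species_prefix + n, node_type="species")
    for n in coexpr.nodes:
        merged.add_node(gene_prefix + n, node_type=gene_type(n))
    for u, v, data in community.edges(data=True):
        merged.add_edge(species_prefix + u, species_prefix + v,
                        edge_type=data.get("edge_type", "co_abundance"))
    for u, v, data in coexpr.edges(data=True):
        merged.add_edge(gene_prefix + u, gene_prefix + v,
                        edge_type=data.get("edge_type", "co_expression"))
    for species, gene, gtype in relations:
        s_id, g_id = species_prefix + species, gene_prefix + gene
        if s_id not in merged:
            merged.add_node(s_id, node_type="species")
        if g_id not in merged:
            merged.add_node(g_id, node_type=gtype)
        merged.add_edge(s_id, g_id, edge_type="literature_relation")
    return merged


def shortest_path_distribution(graph: nx.Graph) -> dict[int, int]:
    """Histogram of finite shortest-path lengths over unordered node pairs."""
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    hist: Counter[int] = Counter()
    for _, dists in nx.all_pairs_shortest_path_length(graph):
        for d in dists.values():
            if d > 0:
                hist[d] += 1
    return {d: c // 2 for d, c in sorted(hist.items())}


def diameter(graph: nx.Graph) -> float:
    """Max finite shortest path, computed on the largest connected component.

    Merged networks contain isolated nodes, so the all-pairs maximum would
    be infinite; restricting to the LCC is the convention used throughout.
    Edgeless graphs have no defined diameter (NaN).
    """
    if graph.number_of_edges() == 0:
        return float("nan")
    lcc = graph.subgraph(max(nx.connected_components(graph), key=len))
    return float(nx.diameter(lcc))


def mean_path_length(graph: nx.Graph) -> float:
    """Mean finite shortest-path length over the LCC's node pairs."""
    if graph.number_of_edges() == 0:
        return float("nan")
    lcc = graph.subgraph(max(nx.connected_components(graph), key=len))
    return float(nx.average_shortest_path_length(lcc))


def largest_component_size(graph: nx.Graph) -> int:
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    return max(len(c) for c in nx.connected_components(graph))


def reachability_profile(
    graph: nx.Graph,
    lengths: tuple[int, ...] = (1, 2, 3),
    start_nodes: list | None = None,
    n_starts: int | None = None,
    seed: int = 0,
) -> dict[int, dict[str, float]]:
    """Mean number of nodes of each type within BFS distance L of a start.

    Averages over all nodes by default (deterministic); ``n_starts`` with
    a seed samples random start nodes instead, reproducing the
    single-random-start variant.  Counts exclude the start node itself.
    """
    if any(l <= 0 for l in lengths):
        raise ValueError("lengths must be positive")
    if start_nodes is None:
        start_nodes = list(graph.nodes)
    if not start_nodes:
        raise ValueError("empty start set")
    if n_starts is not None:
        rng = np.random.default_rng(seed)
        start_nodes = [start_nodes[i] for i in rng.choice(len(start_nodes), size=n_starts, replace=False)]
    types = sorted({graph.nodes[n].get("node_type", "species") for n in graph.nodes})
    max_l = max(lengths)
    totals = {l: {t: 0.0 for t in types} for l in lengths}
    for start in start_nodes:
        dists = nx.single_source_shortest_path_length(graph, start, cutoff=max_l)
        for l in lengths:
            for node, d in dists.items():
                if 0 < d <= l:
                    totals[l][graph.nodes[node].get("node_type", "species")] += 1
    n = len(start_nodes)
    return {l: {t: totals[l][t] / n for t in types} for l in lengths}


@dataclass
class TopologyReport:
    """The topology read-outs for one merged network."""

    n_nodes_by_type: dict[str, int]
    n_edges_by_type: dict[str, int]
    density: float
    diameter: float
    mean_path_length: float
    path_length_histogram: dict[int, int]
    largest_component: int
    reachability: dict[int, dict[str, float]]

    def to_jsonable(self) -> dict:
        return {
            "n_nodes_by_type": self.n_nodes_by_type,
            "n_edges_by_type": self.n_edges_by_type,
            "density": self.density,
            "diameter": None if np.isnan(self.diameter) else self.diameter,
            "mean_path_length": None if np.isnan(self.mean_path_length) else self.mean_path_length,
            "path_length_histogram": {str(k): v for k, v in self.path_length_histogram.items()},
            "largest_component": self.largest_component,
            "reachability": {str(l): by for l, by in self.reachability.items()},
        }


def topology_report(graph: nx.Graph, lengths: tuple[int, ...] = (1, 2, 3)) -> TopologyReport:
    """Compute the full topology summary of a merged typed network."""
    node_types = Counter(d.get("node_type", "species") for _, d in graph.nodes(data=True))
    edge_types = Counter(d.get("edge_type", "unknown") for _, _, d in graph.edges(data=True))
    return TopologyReport(
        n_nodes_by_type=dict(sorted(node_types.items())),
        n_edges_by_type=dict(sorted(edge_types.items())),
        density=float(nx.density(graph)) if graph.number_of_nodes() >= 2 else float("nan"),
        diameter=diameter(graph),
        mean_path_length=mean_path_length(graph),
        path_length_histogram=shortest_path_distribution(graph),
        largest_component=largest_component_size(graph),
        reachability=reachability_profile(graph, lengths=lengths),
    )
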