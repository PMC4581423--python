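import networkx as nx
import numpy as np
import pytest

from feednet import simulate_study
from feednet.data_io import AbundanceTable, ExpressionMatrix


@pytest.fixture(scope="session")
def study():
    """One coherent synthetic study shared by read-only tests."""
    return simulate_study(seed=11)


@pytest.fixture()
def small_abundance():
    return AbundanceTable(
        species_ids=["spA", "spB", "spC"],
        sample_ids=["s1", "s2", "s3", "s4"],
        group=["BF", "BF", "FF", "FF"],
        values=np.array(
            [
                [60.0, 55.0, 10.0, 15.0],
                [30.0, 35.0, 50.0, 45.0],
                [10.0, 10.0, 40.0, 40.0],
            ]
        ),
    )


@pytest.fixture()
def small_expression():
    rng = np.random.default_rng(7)
    return ExpressionMatrix(
        gene_ids=[f"g{i}" for i in range(5)],
        sample_ids=["s1", "s2", "s3", "s4", "s5", "s6"],
        group=["BF"] * 3 + ["FF"] * 3,
        values=rng.normal(8, 1, size=(5, 6)),
    )


@pytest.fixture()
def path_graph_p5():
    g = nx.path_graph(5)
    g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(5)})
    nx.set_node_attributes(g, "species", "node_type")
    nx.set_edge_attributes(g, "co_abundance", "edge_type")
    return g
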