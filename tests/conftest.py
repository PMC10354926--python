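import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pacsi.io import ExpressionMatrix, PhenotypeLabels
from pacsi.network import InteractionNetwork
from pacsi.simulate import SimulationConfig, simulate_dataset

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def path5() -> InteractionNetwork:
    """Path graph a–b–c–d–e (connected, so usable as an LCC)."""
    g = nx.Graph()
    nx.add_path(g, ["a", "b", "c", "d", "e"])
    return InteractionNetwork(g, is_lcc=True)


@pytest.fixture
def small_bulk() -> tuple[ExpressionMatrix, PhenotypeLabels]:
    rng = np.random.default_rng(0)
    df = pd.DataFrame(rng.gamma(2.0, 50.0, size=(40, 8)),
                      index=[f"G{i:02d}" for i in range(40)],
                      columns=[f"S{j}" for j in range(8)])
    labels = PhenotypeLabels([f"S{j}" for j in range(8)],
                             np.array([1, 1, 1, 1, 0, 0, 0, 0]))
    return ExpressionMatrix(df, kind="bulk"), labels


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small simulated benchmark shared by pipeline-level tests."""
    config = SimulationConfig(n_cells=300, n_genes=600, seed=42)
    return simulate_dataset(config, n_case=30, n_control=30,
                            cells_per_sample=100)


def random_connected_graph(rng: np.random.Generator,
                           max_nodes: int = 30) -> InteractionNetwork:
    """Random connected graph (spanning tree plus extra edges)."""
    n = int(rng.integers(4, max_nodes + 1))
    g = nx.Graph()
    nodes = [f"n{i:02d}" for i in range(n)]
    g.add_nodes_from(nodes)
    order = rng.permutation(n)
    for i in range(1, n):  # random spanning tree
        j = int(rng.integers(0, i))
        g.add_edge(nodes[order[i]], nodes[order[j]])
    n_extra = int(rng.integers(0, 2 * n))
    for _ in range(n_extra):
        u, v = rng.integers(0, n, size=2)
        if u != v:
            g.add_edge(nodes[u], nodes[v])
    assert nx.is_connected(g)
    return InteractionNetwork(g, is_lcc=True)
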