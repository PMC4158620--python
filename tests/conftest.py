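import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ccnet.synthetic import SimulationConfig, sample_expression, simulate


@pytest.fixture(scope="session")
def small_truth():
    """A 60-gene synthetic study reused across read-only tests."""
    return simulate(SimulationConfig(n_genes=60, n_samples=120, seed=11))


@pytest.fixture(scope="session")
def medium_truth():
    """300 genes: enough to populate all 24 chromosomes."""
    return simulate(SimulationConfig(n_genes=300, n_samples=20, seed=12))


@pytest.fixture(scope="session")
def small_expression(small_truth):
    return sample_expression(small_truth)


@pytest.fixture()
def toy_positions():
    """Six genes on two chromosomes, 1-based inclusive coordinates."""
    return pd.DataFrame(
        {
            "chromosome": ["1", "1", "1", "2", "2", "2"],
            "start": [100, 5_000, 9_000, 100, 5_000, 9_000],
            "end": [1_099, 5_999, 9_999, 1_099, 5_999, 9_999],
        },
        index=pd.Index(["a", "b", "c", "d", "e", "f"], name="gene"),
    )


def path_graph(labels):
    g = nx.Graph()
    nx.add_path(g, labels)
    return g


@pytest.fixture()
def abc_path():
    return path_graph(["a", "b", "c"])


def random_graph(n, p, seed):
    return nx.relabel_nodes(
        nx.gnp_random_graph(n, p, seed=seed), {i: f"g{i:03d}" for i in range(n)}
    )
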