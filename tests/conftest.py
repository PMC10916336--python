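import networkx as nx
import numpy as np
import pytest

from dva import config, pipeline, synthetic_data


@pytest.fixture()
def path_graph():
    """a - b - c."""
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c")])
    return g


@pytest.fixture()
def triangle():
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c")])
    return g


def make_sbm(n: int, n_blocks: int, p_in: float, p_out: float, seed: int):
    """Two-or-more-block stochastic block model with string node names."""
    rng = np.random.default_rng(seed)
    block = np.repeat(np.arange(n_blocks), n // n_blocks)
    g = nx.Graph()
    names = [f"n{i:03d}" for i in range(n)]
    g.add_nodes_from(names)
    for i in range(n):
        for j in range(i + 1, n):
            p = p_in if block[i] == block[j] else p_out
            if rng.random() < p:
                g.add_edge(names[i], names[j])
    return g, block


@pytest.fixture(scope="session")
def default_config():
    return config.load_config()


@pytest.fixture(scope="session")
def signal_fixture_dir(tmp_path_factory):
    """Default-condition synthetic bundle: 2000 variants, documented effects."""
    d = tmp_path_factory.mktemp("signal_fixture")
    synthetic_data.make_fixture(synthetic_data.SyntheticConfig(seed=1), d)
    return d


@pytest.fixture(scope="session")
def signal_cv_result(signal_fixture_dir, default_config):
    """Tenfold CV of the full pipeline on the default fixture (shared: slow)."""
    return pipeline.cross_validate_fixture(signal_fixture_dir, default_config)
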