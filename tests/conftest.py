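import networkx as nx
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from segc.synthetic import make_example_network

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def example_net():
    """The self-validated 12-node worked-example network."""
    return make_example_network()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_graph(n: int, p: float, seed: int) -> nx.Graph:
    """Erdos-Renyi graph over string-labelled nodes (test helper)."""
    g = nx.gnp_random_graph(n, p, seed=seed)
    return nx.relabel_nodes(g, {i: f"n{i:03d}" for i in g.nodes})
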