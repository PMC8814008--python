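import networkx as nx
import pytest

from lencnet.fixtures import karate_network, toy_network


@pytest.fixture(scope="session")
def toy() -> nx.Graph:
    """6-node, 7-edge golden example network."""
    return toy_network()


@pytest.fixture(scope="session")
def karate() -> nx.Graph:
    """Zachary karate club, 1-based string node ids."""
    return karate_network()
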