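import numpy as np
import pytest

from csrwalign.netio import Network, NetworkSet, SimilarityTable


@pytest.fixture
def toy1():
    """A: u1-u2-u3 path; B: v1-v2 edge; s(u1,v1)=2, s(u2,v2)=1, s(u3,v1)=1."""
    net_a = Network("A", [("u1", "u2"), ("u2", "u3")])
    net_b = Network("B", [("v1", "v2")])
    sim = SimilarityTable("A", "B", {("u1", "v1"): 2.0,
                                     ("u2", "v2"): 1.0,
                                     ("u3", "v1"): 1.0})
    return net_a, net_b, sim


@pytest.fixture
def toy2():
    """A: u1-u2; B: v1-v2-v3 path; s(u1,v1)=1, s(u2,v3)=1 (all moves leave M)."""
    net_a = Network("A", [("u1", "u2")])
    net_b = Network("B", [("v1", "v2"), ("v2", "v3")])
    sim = SimilarityTable("A", "B", {("u1", "v1"): 1.0, ("u2", "v3"): 1.0})
    return net_a, net_b, sim


@pytest.fixture
def toy1_networks(toy1):
    net_a, net_b, _ = toy1
    return NetworkSet([net_a, net_b])


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
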