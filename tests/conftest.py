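import numpy as np
import pytest

from interflux import fixtures
from interflux.networks import NodeNetwork


@pytest.fixture(scope="session")
def star_pair():
    """9-leaf / 4-leaf star pair: every spectral quantity has a closed form."""
    return fixtures.make_star(9), fixtures.make_star(4)


@pytest.fixture(scope="session")
def small_ba_pair():
    """Small scale-free pair for cheap coupled-dynamics tests."""
    netA, netB = fixtures.make_scale_free_pair(N=40, m=2, seedA=3, seedB=4)
    if netA.eigen().lam1 < netB.eigen().lam1:
        netA, netB = netB, netA
    return netA, netB


@pytest.fixture(scope="session")
def ref_pair():
    """The 250+250 reference scale-free pair (default seeds)."""
    return fixtures.make_scale_free_pair()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_undirected_net(rng, n, density=0.3):
    """Random symmetric weighted network, guaranteed at least one link."""
    W = np.triu(rng.uniform(0.1, 2.0, (n, n)) * (rng.random((n, n)) < density), 1)
    if not W.any():
        W[0, -1] = 1.0
    W = W + W.T
    return NodeNetwork(weights=W)
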