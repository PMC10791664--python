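import numpy as np
import pytest

from fconn import WeightedNetwork


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_connected_network(n, rng, density=1.0):
    """Dense random weighted network; connected by construction at density 1."""
    w = rng.uniform(0.05, 0.95, size=(n, n))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    if density < 1.0:
        iu = np.triu_indices(n, k=1)
        drop = rng.random(iu[0].size) > density
        w[iu[0][drop], iu[1][drop]] = 0.0
        w = np.triu(w) + np.triu(w).T
        net = WeightedNetwork(w)
        if not net.is_connected():  # keep fixtures simple: retry denser
            return random_connected_network(n, rng, min(1.0, density + 0.2))
        return net
    return WeightedNetwork(w)


@pytest.fixture()
def network_factory(rng):
    return lambda n, density=1.0: random_connected_network(n, rng, density)
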