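import numpy as np
import pytest

from seqroute.network import NetworkModel, calibrate_profile
from seqroute.synthetic import FixtureSpec, make_fixture_network


@pytest.fixture(scope="session")
def fixture_net_10k():
    """Density-preserving 10,000-neuron fixture with full-size degrees."""
    return make_fixture_network(FixtureSpec(n_neurons=10_000, seed=2))


@pytest.fixture(scope="session")
def small_net():
    """A 2,000-neuron network with scaled-down degree targets, for fast
    dynamical tests."""
    side = 2000.0 * np.sqrt(2000 / 100_000)
    profile = calibrate_profile(
        2000, side, targets={"EE": 150.0, "EI": 30.0, "IE": 300.0, "II": 20.0})
    from seqroute.network import build_network

    return build_network(n_neurons=2000, side=side, profile=profile, seed=11)


def make_chain_network(conductances=(140.0, 140.0), delays=(1.0, 1.5)):
    """Linear chain 0 -> 1 -> ... with given conductances/delays."""
    n = len(conductances) + 1
    pos = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
    return NetworkModel(
        side=float(max(10, n + 1)), positions=pos,
        is_inh=np.zeros(n, dtype=np.uint8),
        pre=np.arange(n - 1, dtype=np.int32),
        post=np.arange(1, n, dtype=np.int32),
        conductance=np.asarray(conductances, dtype=np.float32),
        delay=np.asarray(delays, dtype=np.float32),
    )


@pytest.fixture
def chain_net():
    return make_chain_network()
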