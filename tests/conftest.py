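import numpy as np
import pytest

from cabletune.experiment import ProtocolConfig
from cabletune.substrate import SubstrateConfig


@pytest.fixture(scope="session")
def substrate_cfg():
    """Default substrate: calibrated conductance ranges, OU membrane noise."""
    return SubstrateConfig()


@pytest.fixture(scope="session")
def noiseless_cfg():
    return SubstrateConfig(noise_sigma=0.0)


@pytest.fixture(scope="session")
def white_noise_cfg():
    """White (iid per-sample) read-out noise instead of membrane-filtered."""
    return SubstrateConfig(noise_correlation_time=0.0)


@pytest.fixture(scope="session")
def proto():
    return ProtocolConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_chain(rng, n=5):
    """A physically plausible random chain for oracle comparisons."""
    from cabletune.substrate import ChainModel

    return ChainModel(
        g_l=rng.uniform(0.3, 2.5, n),
        g_ic=rng.uniform(0.3, 4.5, n - 1),
        c_m=rng.uniform(0.5, 2.0, n),
        e_l=np.full(n, 0.25),
    )
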