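import numpy as np
import pytest

from sen1kin import Condition, KineticScheme, TrajectoryConfig


@pytest.fixture
def scheme():
    return KineticScheme()


@pytest.fixture
def condition():
    return Condition(sen1_conc=10e-9, atp_conc=1100.0, n_molecules=1)


@pytest.fixture
def noiseless_config():
    return TrajectoryConfig(duration=40.0, noise_sd=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
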