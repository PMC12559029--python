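import numpy as np
import pytest

import eegunfold as eu


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def synth_config():
    return eu.SyntheticConfig()


@pytest.fixture(scope="session")
def small_unfold_config():
    """A reduced-size unfolded model used throughout the suite: same wiring
    as the default, smaller subnetworks so forward/backward stay fast."""
    return eu.UnfoldConfig(
        K=3,
        netd=eu.NetDConfig(depth=3, channels=(4, 8, 16)),
        netn=eu.NetNConfig(n_layers=2, channels=8),
        netr=eu.NetRConfig(n_layers=2, channels=8),
    )


@pytest.fixture
def mixed_pair(synth_config):
    clean = eu.gen_clean(synth_config, 1, seed=7)[0]
    emg = eu.gen_emg(synth_config, 1, seed=8)[0]
    return clean, emg
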