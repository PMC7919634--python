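import numpy as np
import pytest

from trackinfo import SignalConfig, generate_target


@pytest.fixture(scope="session")
def ar2_target():
    """A long, moderately complex generated target shared across tests."""
    return generate_target(SignalConfig(a1=8.0, n_frames=20_500, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
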