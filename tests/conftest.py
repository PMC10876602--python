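import numpy as np
import pytest

from ofsca import MixSpec, make_mixed_trajectory


@pytest.fixture(scope="session")
def illustration_trajectory():
    """One mixed-fGn trajectory with the standard illustration parameters
    (H1=0.60, H2=0.40, theta1=15 deg, theta2=75 deg, n=10000)."""
    return make_mixed_trajectory(MixSpec(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
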