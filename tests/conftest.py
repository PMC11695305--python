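import numpy as np
import pytest

from saltprofile.synthetic import ProfileConfig, generate_profiles


@pytest.fixture(scope="session")
def default_samples():
    """Default synthetic campaign: 18 sites x 5 layers x 4 periods."""
    return generate_profiles(ProfileConfig(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
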