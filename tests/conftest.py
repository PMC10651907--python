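import numpy as np
import pytest

from activegaze.simulate import BehaviorParams, NoiseParams, generate_design


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_design():
    return generate_design(n_subjects=3, n_trials=18, seed=11)


@pytest.fixture(scope="session")
def quiet_params():
    """Simulator parameters with sensor noise disabled."""
    return BehaviorParams(noise=NoiseParams(enabled=False))


@pytest.fixture(scope="session")
def noisy_params():
    return BehaviorParams()
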