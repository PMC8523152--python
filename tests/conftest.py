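import numpy as np
import pytest

from reachkin.synthetic_data import ReachModelParams, make_targets


@pytest.fixture(scope="session")
def targets():
    return make_targets()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_params():
    return ReachModelParams(seed=7)


@pytest.fixture
def noiseless_params():
    return ReachModelParams(sigma_plan=0.0, bias=(0.0, 0.0), sigma_exec=0.0,
                            sigma_fb=0.0, feedback_gain=1.0, seed=7)


@pytest.fixture
def moderate_params():
    """Noise levels typical of a prosthesis-user reach."""
    return ReachModelParams(sigma_plan=4.0, bias=(0.3, 0.2), sigma_exec=1.2,
                            sigma_fb=0.4, feedback_gain=0.9, seed=7)
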