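import pytest

from rivalnorm import ModelParams, NoiseParams
from rivalnorm.dynamics import DynamicsParams
from rivalnorm.experiments import exp1_condition, exp2_condition


@pytest.fixture(scope="session")
def default_model():
    return ModelParams()


@pytest.fixture(scope="session")
def zero_noise_model():
    """Effectively noise-free model with the gain always on the dominant."""
    return ModelParams(
        noise=NoiseParams(lower=-1e-12, upper=1e-12),
        dynamics=DynamicsParams(gain_bias=1.0),
    )


@pytest.fixture
def green_bg():
    return exp1_condition("green")


@pytest.fixture
def gray_bg():
    return exp1_condition("gray")


@pytest.fixture
def rivalrous_bg():
    return exp2_condition()
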