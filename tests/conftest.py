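import numpy as np
import pytest

from aortagen import default_parameters
from aortagen.meshgen import generate_model


@pytest.fixture(scope="session")
def type_i_params():
    return default_parameters("I")


@pytest.fixture(scope="session")
def type_ii_params():
    return default_parameters("II")


@pytest.fixture(scope="session")
def model_i():
    """Type I model at default resolution, shared across measurement tests."""
    return generate_model("I")


@pytest.fixture(scope="session")
def model_ii():
    return generate_model("II")


@pytest.fixture
def rng():
    return np.random.default_rng(17)
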