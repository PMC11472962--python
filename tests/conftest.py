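import numpy as np
import pytest

from dualaddiction import ModelParameters
from dualaddiction.cli_io import find_backward_parameters, fixture_params


@pytest.fixture(scope="session")
def baseline_params() -> ModelParameters:
    """The baseline calibration used throughout the documentation examples."""
    return ModelParameters()


@pytest.fixture(scope="session")
def forward_params() -> ModelParameters:
    """A supercritical (R0 > 1) regime with a unique endemic equilibrium."""
    return fixture_params(3, "forward")


@pytest.fixture(scope="session")
def backward_params() -> ModelParameters:
    """A certified subcritical regime with two positive endemic roots."""
    return find_backward_parameters(7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
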