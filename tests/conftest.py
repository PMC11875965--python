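import numpy as np
import pytest

from emgmm.activation import ActivationConstants
from emgmm.model import DynamicsConfig
from emgmm.synthetic import (
    generate_subject_cycles,
    make_generic_params,
    sample_subject,
)


@pytest.fixture(scope="session")
def generic():
    return make_generic_params()


@pytest.fixture(scope="session")
def constants():
    return ActivationConstants()


@pytest.fixture(scope="session")
def dynamics():
    return DynamicsConfig()


@pytest.fixture(scope="session")
def subject():
    """One perturbed synthetic subject (rho = 0.2)."""
    return sample_subject(seed=7, rho=0.2)


@pytest.fixture(scope="session")
def cycles(subject):
    """Six data cycles of the shared subject (default 1 deg angle noise)."""
    return generate_subject_cycles(subject, 6)


@pytest.fixture(scope="session")
def clean_cycles(subject):
    """Noise-free cycles of the shared subject (sigma = 0)."""
    return generate_subject_cycles(subject, 3, sigma_deg=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
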