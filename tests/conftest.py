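import numpy as np
import pytest

from latgen import build_design, generate_blocked_generalization
from latgen.activation_models import ActivationParams


@pytest.fixture(scope="session")
def design():
    return build_design(0)


@pytest.fixture(scope="session")
def blocked_seq(design):
    return generate_blocked_generalization(design, 3)


@pytest.fixture(scope="session")
def mid_params():
    """The worked-example rates: distinct powers stay distinguishable."""
    return ActivationParams(0.5, 0.2, 0.1)


@pytest.fixture(scope="session")
def canonical_params():
    """Rates in the ordering observed empirically: a1 > a2 > a3."""
    return ActivationParams(0.9, 0.5, 0.1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
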