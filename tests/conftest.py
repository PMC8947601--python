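import numpy as np
import pytest

from evoforage import BirthRates, exponential_weights, generate_lattice


@pytest.fixture
def uniform_weights():
    return exponential_weights(0.0, 5)


@pytest.fixture
def abm_births():
    """Birth rates of the lattice simulations."""
    return BirthRates(np.array([0.0, 1.0, 2.0, 3.0, 4.0]))


@pytest.fixture
def mf_births():
    """Birth rates of the mean-field runs."""
    return BirthRates(np.array([0.0, 1.0, 2.0, 3.0, 5.0]))


@pytest.fixture
def small_lattice(uniform_weights):
    return generate_lattice(32, uniform_weights, seed=7)
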