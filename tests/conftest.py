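import numpy as np
import pytest

from clonaltrace import synthetic_data


@pytest.fixture(scope="session")
def model():
    return synthetic_data.default_model(seed=7)


@pytest.fixture(scope="session")
def noise_free_model():
    m = synthetic_data.default_model(seed=7)
    m.noise_cv = 0.0
    m.biomass_cv = 0.0
    m.atom_noise_sd = 0.0
    return m


@pytest.fixture(scope="session")
def truth(model):
    return synthetic_data.ground_truth(model)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260101)
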