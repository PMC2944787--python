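import numpy as np
import pytest

from capmap.scenarios import (
    default_scenario,
    density_scenario,
    tumour_scenario,
    x_inactivation_scenario,
)

#: Seed of the reference desk-scale study used across the suite.
STUDY_SEED = 1


@pytest.fixture(scope="session")
def default_bundle():
    return default_scenario(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def density_bundle():
    return density_scenario(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def x_bundle():
    return x_inactivation_scenario(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def tumour_bundle():
    return tumour_scenario(seed=STUDY_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(STUDY_SEED)
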