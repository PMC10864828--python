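import numpy as np
import pytest

from growthsim import GrowthPopulation
from growthsim.study import LINEAR_ALPHA, LINEAR_PSI, QUADRATIC_ALPHA, QUADRATIC_PSI


@pytest.fixture(scope="session")
def linear_pop():
    return GrowthPopulation("linear", LINEAR_ALPHA, LINEAR_PSI)


@pytest.fixture(scope="session")
def quadratic_pop():
    return GrowthPopulation("quadratic", QUADRATIC_ALPHA, QUADRATIC_PSI)


@pytest.fixture(scope="session")
def linear_psi():
    return np.array(LINEAR_PSI)
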