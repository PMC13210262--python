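import numpy as np
import pytest

from pedallo import PopulationPKParams, synthetic_lms_table


@pytest.fixture(scope="session")
def lms_table():
    return synthetic_lms_table()


@pytest.fixture(scope="session")
def pop():
    """Default population parameters of the hypothetical mAb."""
    return PopulationPKParams()


@pytest.fixture(scope="session")
def noise_free_pop():
    """All inter-individual and residual variability switched off."""
    return PopulationPKParams(cv_v=0.0, cv_cl=0.0, cv_ka=0.0, corr_v_cl=0.0,
                              sigma_prop=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20250925)
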