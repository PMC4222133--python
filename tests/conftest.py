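import numpy as np
import pytest

from spmaging.presets import study_params, study_scheme
from spmaging.simulate import simulate_cohort


@pytest.fixture(scope="session")
def params():
    return study_params()


@pytest.fixture(scope="session")
def scheme():
    return study_scheme()


@pytest.fixture(scope="session")
def cohort(params, scheme):
    """Small reference cohort shared by read-only tests."""
    return simulate_cohort(params, 200, scheme, rng=12345)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
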