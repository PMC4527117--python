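import numpy as np
import pytest

from madaccel.pipeline import extract_bout_mads, heart_rate_table
from madaccel.synthetic import generate_cohort

COHORT_SEED = 7


@pytest.fixture(scope="session")
def default_cohort():
    """Full 20-participant, two-device protocol cohort (generated once)."""
    return generate_cohort(20, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def mad_table(default_cohort):
    return extract_bout_mads(default_cohort)


@pytest.fixture(scope="session")
def hr_table(default_cohort):
    return heart_rate_table(default_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
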