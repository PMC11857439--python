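import numpy as np
import pytest

from striatnorm import synthetic as syn


@pytest.fixture(scope="session")
def cohort():
    """Default 116-subject cohort."""
    return syn.generate_cohort(seed=1)


@pytest.fixture(scope="session")
def roi_table(cohort):
    """Default calibrated ROI uptake table for the default cohort."""
    return syn.generate_roi_suv(cohort, seed=2)


@pytest.fixture(scope="session")
def atlas():
    return syn.generate_atlas()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
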