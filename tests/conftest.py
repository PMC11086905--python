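import numpy as np
import pytest

from shapform import SyntheticConfig, default_item_bank, generate_cohort


@pytest.fixture(scope="session")
def bank():
    return default_item_bank()


@pytest.fixture(scope="session")
def small_cohort():
    """n=800 default-calibration cohort shared by the slower tests."""
    return generate_cohort(SyntheticConfig.default(n=800, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
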