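import numpy as np
import pytest

from hypersurv.simulate import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    cohort, truth = generate_cohort(SyntheticConfig(n=60, seed=42))
    return cohort, truth


@pytest.fixture(scope="session")
def big_cohort():
    """Shared n=2,000 draw for marginal / calibration checks."""
    cohort, truth = generate_cohort(SyntheticConfig(n=2000, seed=7))
    return cohort, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
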