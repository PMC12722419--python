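import numpy as np
import pytest

from umevo import SimConfig, simulate_cohort, analyze_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """An 80-patient default-condition cohort shared across read-only tests."""
    return simulate_cohort(SimConfig(n_patients=80, seed=11))


@pytest.fixture(scope="session")
def small_estimates(small_cohort):
    return analyze_cohort(small_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
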