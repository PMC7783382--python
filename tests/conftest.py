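import warnings

import pytest

from t2titrate.cohort import CohortConfig
from t2titrate.conduct import TrialConfig, run_trial

warnings.filterwarnings("ignore", message="eosinophil count")


@pytest.fixture(scope="session")
def small_config() -> TrialConfig:
    """An 80-patient trial configuration used across test modules."""
    return TrialConfig(cohort=CohortConfig(n=80))


@pytest.fixture(scope="session")
def small_trial(small_config):
    """One simulated 80-patient trial (seed 11)."""
    return run_trial(small_config, seed=11)


@pytest.fixture(scope="session")
def full_trial():
    """A full-size (n=301) simulated trial (seed 5)."""
    return run_trial(TrialConfig(), seed=5)
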