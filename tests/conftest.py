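import logging

import pytest
from hypothesis import HealthCheck, settings

from bsiepi import SyntheticCohortConfig, simulate_cohort

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

# classify_onset logs a warning per outpatient-only episode; keep test output readable
logging.getLogger("bsiepi").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-rate cohort (~170 episodes) shared across tests."""
    return simulate_cohort(SyntheticCohortConfig(n_patients=150, seed=5))


@pytest.fixture(scope="session")
def noise_free_cohort():
    """A cohort whose physician labels equal the planted truth exactly."""
    cfg = SyntheticCohortConfig(
        n_patients=300,
        seed=7,
        physician_discordance={
            "contamination": 0.0, "polymicrobial": 0.0, "onset": 0.0, "hca": 0.0,
        },
    )
    return simulate_cohort(cfg)
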