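import numpy as np
import pytest

from resilsense import synthetic as syn


@pytest.fixture(scope="session")
def small_cohort():
    """A quick deterministic cohort shared by read-only tests."""
    cfg = syn.CohortConfig(
        n_participants=60, baseline_weeks=2, days_per_quarter=4, seed=42
    )
    return syn.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def plain_config():
    """Identity-shift configuration: no clusters, no pulls, no jitter, no
    multi-hour cycle lumping — baseline and internship share one generating
    process."""
    return syn.CohortConfig(
        n_participants=120,
        baseline_weeks=3,
        days_per_quarter=6,
        shift_clusters=(syn.ShiftCluster(weight=1.0),),
        sleep_lump_prob=0.0,
        shift_jitter_sd=0.0,
        sleep_shift_coupling=0.0,
        mood_pull=0.0,
        hr_pull=0.0,
        steps_pull=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
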