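import numpy as np
import pytest

from opposcreen.core_io import Sample, TaskGeometry, TrialTrajectory, SessionRecord
from opposcreen.synthetic import CohortSpec, MotorProfile, cts_profile, simulate_cohort


@pytest.fixture(scope="session")
def geometry():
    return TaskGeometry()


@pytest.fixture(scope="session")
def noise_free_profile():
    """Fully deterministic profile: no tremor, no timing jitter, no timeouts."""
    return MotorProfile(tremor_sd=0.0, timeout_prob=0.0,
                        hand_speed_cv=0.0, time_jitter_cv=0.0)


@pytest.fixture(scope="session")
def small_cohort():
    """Compact labelled cohort shared across I/O and pipeline tests."""
    spec = CohortSpec(n_healthy=6, n_cts=6, seed=11)
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def study_cohort():
    """Default-sized cohort (27 unimpaired / 36 impaired hands)."""
    return simulate_cohort(CohortSpec(seed=5))


def straight_trial(direction=12, lap=2, duration=1.0, distance=2.0, n=11,
                   collected=True):
    """Constant-speed straight reach upward; helper for analytic cases."""
    ts = np.linspace(0.0, duration, n)
    samples = [Sample(float(t), 0.0, float(distance * t / duration)) for t in ts]
    return TrialTrajectory(direction, lap, samples, collected,
                           duration if collected else None)
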