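import numpy as np
import pytest

from gaitlstm import (CohortConfig, make_cohort, build_cycles,
                      sample_subject_profile, SubjectProfile)


@pytest.fixture(scope="session")
def small_cohort():
    """Two-subject default-noise cohort used by several structural tests."""
    cfg = CohortConfig(n_subjects=2, min_cycles=16, max_cycles=16, seed=42)
    trials, manifest = make_cohort(cfg)
    return cfg, trials, manifest


@pytest.fixture(scope="session")
def small_cycles(small_cohort):
    _, trials, _ = small_cohort
    cycles = []
    for t in trials:
        cycles.extend(build_cycles(t))
    return cycles


@pytest.fixture(scope="session")
def noise_free_trial():
    cfg = CohortConfig(n_subjects=1, min_cycles=8, max_cycles=8,
                       seed=7).noise_free()
    trials, _ = make_cohort(cfg)
    return trials[0]


@pytest.fixture
def default_profile():
    cfg = CohortConfig(seed=0)
    rng = np.random.default_rng(123)
    return sample_subject_profile(cfg, rng, subject_id=0)


def standing_profile() -> SubjectProfile:
    """Zero-speed profile for statics checks."""
    return SubjectProfile(subject_id=0, speed_mps=0.0, cadence_spm=100.0,
                          stride_m=0.0, thigh_m=0.42, shank_m=0.40,
                          accel_noise_g=0.0, gyro_noise_dps=0.0,
                          attitude_noise_deg=0.0, cycle_jitter=0.0)
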