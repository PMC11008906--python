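import numpy as np
import pytest

from ecgage.beats import NNSeries
from ecgage.synthetic import (
    SyntheticCohortConfig,
    default_age_profile,
    generate_cohort,
    synthesize_record,
)


def make_nn(intervals_ms, t0=1.0):
    """NNSeries with timestamps accumulated from the intervals themselves."""
    intervals_ms = np.asarray(intervals_ms, dtype=float)
    ts = t0 + np.cumsum(intervals_ms) / 1000.0
    return NNSeries(intervals_ms=intervals_ms, timestamps_s=ts, n_rejected=0)


@pytest.fixture(scope="session")
def clean_record():
    """One noise-free synthetic record with exact generator annotations."""
    cfg = SyntheticCohortConfig(
        subjects_per_group=1, duration_s=60.0, noise_std_mv=0.0, seed=5,
        amplitude_jitter_rel=0.0, hr_jitter_bpm=0.0, breathing_jitter_bpm=0.0,
    )
    return synthesize_record(3, default_age_profile(), cfg, seed=11)


@pytest.fixture(scope="session")
def noisefree_cohort():
    """Noise-free 15-group cohort (1 subject per group) for fiducial checks."""
    cfg = SyntheticCohortConfig(subjects_per_group=1, duration_s=60.0, noise_std_mv=0.0, seed=5)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    """Default-profile cohort at smoke scale (15 x 3 subjects, 60 s)."""
    cfg = SyntheticCohortConfig(subjects_per_group=3, duration_s=60.0, seed=42)
    return generate_cohort(cfg)
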