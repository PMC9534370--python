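import numpy as np
import pytest

from painquant import SynthConfig, simulate_cohort
from painquant.core_io import PULSE_SITES, TEMP_SITES, RawRecording


def make_recording(n=800, fs=66.67, subject="S01", rid="S01R01",
                   pain_start=3, pain_end=5, fill=0.0):
    """Minimal well-formed recording with constant channels."""
    duration = n / fs
    return RawRecording(
        subject_id=subject, recording_id=rid, fs=fs,
        pulse={s: np.full(n, fill, dtype=float) for s in PULSE_SITES},
        temperature={s: np.full(n, 30.0 + i, dtype=float)
                     for i, s in enumerate(TEMP_SITES)},
        pain_start=pain_start, pain_end=pain_end, duration_s=duration,
    )


NOISE_FREE_KW = dict(
    base_ibi_s=0.8, rise_fraction_base=0.3, ibi_jitter_sd_s=0.0,
    artifact_fraction=0.0, coupling={}, pulse_noise_sd=0.0,
    temp_noise_sd=0.0, temp_drift_sd=0.0, subject_ibi_sd=0.0, subject_temp_sd=0.0,
)


@pytest.fixture(scope="session")
def noise_free_recording():
    """One 120-s recording with zero jitter, noise and artifacts."""
    cfg = SynthConfig(n_subjects=1, recordings_per_subject=1, duration_s=120.0,
                      seed=2, **NOISE_FREE_KW)
    return simulate_cohort(cfg)[0]


@pytest.fixture(scope="session")
def small_cohort():
    """3 subjects x 3 recordings x 90 s with default coupling and artifacts."""
    cfg = SynthConfig(n_subjects=3, recordings_per_subject=3, duration_s=90.0, seed=11)
    return simulate_cohort(cfg)
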