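import numpy as np
import pytest

from ecgsync import RhythmSpec, Signal, generate_record_pair, resample


@pytest.fixture(scope="session")
def clean_record():
    """60 s two-lead record, regular 60 bpm sinus rhythm, no ectopy."""
    lead_i, lead_v2, r_times = generate_record_pair(
        60, RhythmSpec(mean_hr=60, rr_jitter_sd=0.0, ectopy_rate=0.0), seed=42
    )
    return lead_i, lead_v2, r_times


@pytest.fixture(scope="session")
def jittered_record():
    """120 s two-lead record with physiological RR jitter and sparse ectopy."""
    lead_i, lead_v2, r_times = generate_record_pair(
        120, RhythmSpec(mean_hr=70, rr_jitter_sd=0.04, ectopy_rate=0.05), seed=7
    )
    return lead_i, lead_v2, r_times


@pytest.fixture
def sine_250():
    def make(freq, duration=20.0, fs=250.0):
        t = np.arange(int(duration * fs)) / fs
        return Signal(np.sin(2 * np.pi * freq * t), fs=fs)

    return make


@pytest.fixture(scope="session")
def clean_lead_250(clean_record):
    """Clean lead I resampled to the 250 Hz working rate."""
    return resample(clean_record[0], 250.0)
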