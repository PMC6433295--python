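"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pandas as pd
import pytest

from pafpipe import EpochSet, SimConfig, generate_cohort, generate_subject_epochs


def make_epochs(data, fs=160.0, t0=-800.0, channels=None, trials=None, **kw):
    """EpochSet around a raw array with defaults filled in."""
    data = np.asarray(data, dtype=float)
    times = t0 + 1000.0 / fs * np.arange(data.shape[2])
    channels = channels or [f"c{i}" for i in range(data.shape[1])]
    trials = trials if trials is not None else pd.DataFrame(
        {"percept": ["EM"] * data.shape[0]}
    )
    return EpochSet(data, fs, times, channels, trials, **kw)


def sinusoid_epochs(freq_hz, n_trials=1, n_channels=1, fs=160.0, t0=-800.0,
                    dur_s=2.0, amplitude=1.0, phase=0.0):
    t = np.arange(0, dur_s, 1.0 / fs)
    x = amplitude * np.sin(2 * np.pi * freq_hz * t + phase)
    data = np.tile(x, (n_trials, n_channels, 1))
    return make_epochs(data, fs=fs, t0=t0)


@pytest.fixture(scope="session")
def high_snr_subject():
    """One subject with near-noiseless alpha and a 0.4 Hz GM offset."""
    cfg = SimConfig(n_subjects=2, n_trials_per_condition=20, n_channels=16,
                    snr=50.0, freq_offset_gm=0.4, freq_jitter_sd=0.3, seed=11)
    return generate_subject_epochs(cfg, 0)


@pytest.fixture(scope="session")
def small_coupled_cohort():
    """8 subjects, modest trial counts, percept-coupled frequency."""
    cfg = SimConfig(n_subjects=8, n_trials_per_condition=30, n_channels=16,
                    freq_offset_gm=0.5, snr=2.0, seed=5)
    return generate_cohort(cfg)
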