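"""Shared fixtures: small synthetic physiology objects, generated at test
time (module/session scope where construction is expensive)."""

import numpy as np
import pytest

from cardiofuse.records import ECG_FS, PPG_FS, WaveformRecord
from cardiofuse.synthetic_cohort import (
    CouplingParams, PatientMeta, TrajectoryParams, emulate_pac_stream,
    simulate_ci_trajectory, synthesize_waveforms,
)


@pytest.fixture(scope="session")
def patient():
    return PatientMeta("P0", height_cm=167.0, weight_kg=63.0)


@pytest.fixture(scope="session")
def clean_coupling():
    return CouplingParams(noise_sd=0.0, seed=3)


@pytest.fixture(scope="session")
def drift_trajectory():
    """600 s smoothly drifting CI trajectory."""
    return simulate_ci_trajectory(600.0, rng_seed=1)


@pytest.fixture(scope="session")
def constant_trajectory():
    return simulate_ci_trajectory(
        600.0,
        TrajectoryParams(baseline=2.0, drift_amplitude=0.0, walk_sd=0.0),
        rng_seed=0,
    )


@pytest.fixture(scope="session")
def clean_waveforms(patient, drift_trajectory, clean_coupling):
    """Noise-free ECG/PPG for the drifting trajectory."""
    return synthesize_waveforms(patient, drift_trajectory, clean_coupling)


@pytest.fixture(scope="session")
def constant_waveforms(patient, constant_trajectory, clean_coupling):
    """Noise-free ECG/PPG at constant CI (strictly periodic beats)."""
    return synthesize_waveforms(patient, constant_trajectory, clean_coupling)


@pytest.fixture(scope="session")
def pac_stream(patient, drift_trajectory):
    return emulate_pac_stream(patient, drift_trajectory)


def sinusoid_record(freq_hz, fs, duration_s, modality="PPG", amp=1.0):
    t = np.arange(int(duration_s * fs)) / fs
    return WaveformRecord(
        samples=amp * np.sin(2 * np.pi * freq_hz * t), fs=fs, t0=0.0,
        modality=modality,
    )
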