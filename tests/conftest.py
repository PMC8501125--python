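import numpy as np
import pytest

from gaitsteps import (
    GaitSimConfig,
    ProtocolSpec,
    ResultantSeries,
    TriaxialRecording,
    simulate_recording,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_series():
    """A constant 1 g resultant, 10 s at 100 Hz (a sensor at rest)."""
    t = np.arange(1000) / 100.0
    return ResultantSeries(t=t, r=np.ones(1000), fs=100.0)


def make_pulse_series(peaks, fs=100.0, duration=None, baseline=1.0, sigma=0.025):
    """Resultant with Gaussian bumps at given (time, amplitude-above-baseline)."""
    duration = duration or (max(t for t, _ in peaks) + 1.0)
    t = np.arange(int(round(duration * fs))) / fs
    r = np.full_like(t, baseline)
    for tk, ak in peaks:
        r += ak * np.exp(-0.5 * ((t - tk) / sigma) ** 2)
    return ResultantSeries(t=t, r=r, fs=fs)


@pytest.fixture
def pulse_series():
    return make_pulse_series([(1.0, 1.0), (2.0, 1.0), (3.0, 1.0)], duration=4.0)


@pytest.fixture
def quiet_config():
    """Noiseless, jitter-free simulator settings for exact-recovery tests."""
    return GaitSimConfig(noise_sd_g=0.0, cadence_jitter_sd=0.0, step_jitter_sd=0.0,
                         ramp_range_s=(5.0, 5.0))


@pytest.fixture
def short_protocol():
    return ProtocolSpec.from_speeds([3.0, 4.5], segment_duration_s=60.0)


@pytest.fixture
def noisy_subject(short_protocol):
    return simulate_recording(GaitSimConfig(), short_protocol, seed=77)


def random_recording(rng, duration=10.0, fs=100.0):
    """A noisy recording with randomly spaced, non-overlapping bumps.

    Bump separation stays above 0.3 s so each impulse yields its own
    supra-threshold excursion (gait-like spacing).
    """
    t = np.arange(int(duration * fs)) / fs
    r = 1.0 + 0.03 * rng.standard_normal(len(t))
    times = []
    clock = 0.5
    while clock < duration - 0.5:
        times.append(clock)
        clock += rng.uniform(0.3, 0.9)
    for tk in times:
        r += rng.uniform(0.3, 1.5) * np.exp(-0.5 * ((t - tk) / 0.025) ** 2)
    r = np.abs(r)
    ax = r / np.sqrt(3) + 0.01 * rng.standard_normal(len(t))
    ay = r / np.sqrt(3) + 0.01 * rng.standard_normal(len(t))
    az = np.sqrt(np.maximum(r**2 - ax**2 - ay**2, 0.0))
    return TriaxialRecording(t, ax, ay, az, fs)
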