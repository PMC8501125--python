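"""Synthetic treadmill-gait recordings with exact ground truth.

The generator targets the detector's feature space rather than full gait
biomechanics: each step is a smooth positive bump on a 1 g gravity baseline
of the resultant, planted at a cadence that rises with treadmill speed, with
Gaussian sensor noise on each axis.  A fixed per-subject unit orientation
vector distributes the resultant across the three axes, so the vector norm
recovers the planted waveform exactly.  Every planted step's peak time is
recorded, giving exact per-segment ground-truth counts — the synthetic
analogue of video-counted steps.

Speed stages follow the treadmill protocol structure: 4-minute stages with a
5–10 s acceleration ramp at each stage start, during which cadence and bump
amplitude interpolate linearly from the previous stage's values (from a
reduced "getting under way" level on the first stage).  Ramp steps belong to
the stage that contains them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .energy import ICTrace, ML_O2_PER_KG_MIN_PER_MET
from .protocol import ProtocolSegment, ProtocolSpec
from .raw_signal import TriaxialRecording

__all__ = [
    "GaitSimConfig",
    "SimulatedSubject",
    "simulate_recording",
    "simulate_cohort",
    "simulate_ic_trace",
]

#: Default cadence per treadmill speed, steps/min.  Plausible adult values
#: rising with speed; package defaults, not measurements from any study.
DEFAULT_CADENCE_SPM = {1.5: 70.0, 3.0: 95.0, 4.5: 110.0, 6.0: 120.0, 9.0: 150.0, 10.5: 160.0}

#: Default step-bump peak amplitude above the 1 g baseline, in g.
DEFAULT_AMPLITUDE_G = {1.5: 0.4, 3.0: 0.8, 4.5: 1.1, 6.0: 1.4, 9.0: 2.1, 10.5: 2.5}


@dataclass(frozen=True)
class GaitSimConfig:
    """Knobs of the gait generator; defaults emulate a lab treadmill protocol."""

    cadence_spm: dict[float, float] = field(
        default_factory=lambda: dict(DEFAULT_CADENCE_SPM))
    amplitude_g: dict[float, float] = field(
        default_factory=lambda: dict(DEFAULT_AMPLITUDE_G))
    impulse_width_s: float = 0.10     # ~full width of the step bump (4 sigma)
    noise_sd_g: float = 0.05          # per-axis Gaussian sensor noise
    cadence_jitter_sd: float = 0.05   # per-subject multiplicative cadence sd
    step_jitter_sd: float = 0.03      # per-step multiplicative gap sd
    ramp_range_s: tuple[float, float] = (5.0, 10.0)
    baseline_g: float = 1.0
    first_stage_cadence_frac: float = 0.6  # ramp start level on the first stage
    first_stage_amplitude_frac: float = 0.5
    fs: float = 100.0

    def __post_init__(self):
        speeds = sorted(self.cadence_spm)
        if speeds != sorted(self.amplitude_g):
            raise ValueError("cadence and amplitude tables must cover the same speeds")
        cad = [self.cadence_spm[v] for v in speeds]
        if any(b <= a for a, b in zip(cad, cad[1:])):
            raise ValueError("cadence must be strictly increasing with speed")
        if any(a <= self.noise_sd_g for a in self.amplitude_g.values()):
            raise ValueError("bump amplitudes must exceed the noise sd")
        lo, hi = self.ramp_range_s
        if not (0 < lo <= hi):
            raise ValueError("invalid ramp range")


@dataclass(frozen=True)
class SimulatedSubject:
    """One synthetic recording with exact step-time ground truth."""

    recording: TriaxialRecording
    segments: tuple[ProtocolSegment, ...]   # true_steps filled in
    true_step_times: np.ndarray
    ic_trace: ICTrace | None = None

    @property
    def true_total(self) -> int:
        return int(sum(s.true_steps for s in self.segments))


def _lookup(table: dict[float, float], speed: float, what: str) -> float:
    for k, v in table.items():
        if math.isclose(k, speed):
            return v
    raise ValueError(f"no {what} configured for speed {speed} km/h")


def simulate_recording(
    config: GaitSimConfig, protocol: ProtocolSpec, seed
) -> SimulatedSubject:
    """Generate one subject's triaxial recording for a speed protocol.

    ``seed`` may be an int or a :class:`numpy.random.SeedSequence`.  A fixed
    seed reproduces the recording bit for bit.
    """
    rng = np.random.default_rng(seed)
    fs = config.fs
    cad_mult = max(0.1, 1.0 + rng.normal(0.0, config.cadence_jitter_sd))

    # fixed subject orientation: unit vector carrying the resultant
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)

    segs = list(protocol.segments)
    t0, t1 = segs[0].start_s, segs[-1].end_s
    n = int(round((t1 - t0) * fs))
    t = t0 + np.arange(n) / fs

    sigma = config.impulse_width_s / 4.0
    min_gap = config.impulse_width_s
    step_times: list[float] = []
    step_amps: list[float] = []

    prev_cad = prev_amp = None
    clock = None
    for seg in segs:
        cad_target = _lookup(config.cadence_spm, seg.speed_kmh, "cadence") * cad_mult
        amp_target = _lookup(config.amplitude_g, seg.speed_kmh, "amplitude")
        if prev_cad is None:
            cad_from = cad_target * config.first_stage_cadence_frac
            amp_from = amp_target * config.first_stage_amplitude_frac
        else:
            cad_from, amp_from = prev_cad, prev_amp
        ramp = min(rng.uniform(*config.ramp_range_s), seg.duration_s)

        def _at(tau: float) -> tuple[float, float]:
            """cadence/amplitude at time tau within this segment."""
            x = (tau - seg.start_s) / ramp
            if x >= 1.0:
                return cad_target, amp_target
            return (cad_from + (cad_target - cad_from) * x,
                    amp_from + (amp_target - amp_from) * x)

        if clock is None:
            cad0, _ = _at(seg.start_s)
            clock = seg.start_s + 0.5 * 60.0 / cad0
        while clock < seg.end_s:
            cad, amp = _at(clock)
            step_times.append(clock)
            step_amps.append(amp)
            gap = 60.0 / cad * (1.0 + rng.normal(0.0, config.step_jitter_sd))
            if gap < min_gap:
                raise ValueError(
                    f"cadence {cad:.0f} steps/min leaves gap {gap:.3f} s below the "
                    f"impulse width {min_gap} s; impulses would overlap"
                )
            clock += gap
        prev_cad, prev_amp = cad_target, amp_target

    # resultant waveform: baseline + sum of Gaussian bumps (windowed +-5 sigma)
    r = np.full(n, config.baseline_g)
    half = int(np.ceil(5 * sigma * fs))
    for tk, ak in zip(step_times, step_amps):
        c = int(round((tk - t0) * fs))
        lo, hi = max(0, c - half), min(n, c + half + 1)
        r[lo:hi] += ak * np.exp(-0.5 * ((t[lo:hi] - tk) / sigma) ** 2)

    axes = np.abs(u)[:, None] * r[None, :]  # |u| keeps each axis non-negative at rest
    axes = axes + rng.normal(0.0, config.noise_sd_g, size=axes.shape)
    rec = TriaxialRecording(t, axes[0], axes[1], axes[2], fs)

    times = np.asarray(step_times)
    filled = tuple(
        seg.with_true_steps(int(np.count_nonzero((times >= seg.start_s) & (times < seg.end_s))))
        for seg in segs
    )
    return SimulatedSubject(recording=rec, segments=filled, true_step_times=times)


def simulate_cohort(
    n_subjects: int, protocol: ProtocolSpec, config: GaitSimConfig, seed
) -> list[SimulatedSubject]:
    """Independent subjects with per-subject seeds spawned from a master seed."""
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    return [simulate_recording(config, protocol, child)
            for child in ss.spawn(n_subjects)]


def simulate_ic_trace(
    protocol: ProtocolSpec,
    met_per_speed: dict[float, float],
    body_mass_kg: float,
    seed,
    *,
    noise_sd: float = 0.05,
) -> ICTrace:
    """Per-minute VO2/VCO2 consistent with a MET level per speed stage.

    VO2 (ml/min) = MET × 3.5 × mass with multiplicative noise; VCO2 = RER ×
    VO2 with RER drawn uniformly inside the physiologic band [0.7, 0.99], so
    the trace never triggers RER flags by construction.
    """
    for v in met_per_speed.values():
        if v < 1:
            raise ValueError("MET levels below 1 are not physiologic inputs here")
    rng = np.random.default_rng(seed)
    minutes = int(round(protocol.total_duration_s / 60.0))
    t0 = protocol.segments[0].start_s
    vo2 = np.empty(minutes)
    for m in range(minutes):
        mid = t0 + 60.0 * m + 30.0
        seg = next((s for s in protocol.segments if s.start_s <= mid < s.end_s),
                   protocol.segments[-1])
        met = _lookup(met_per_speed, seg.speed_kmh, "MET")
        vo2[m] = met * ML_O2_PER_KG_MIN_PER_MET * body_mass_kg * (
            1.0 + rng.normal(0.0, noise_sd))
    rer = rng.uniform(0.7, 0.99, size=minutes)
    return ICTrace(vo2_ml_min=np.maximum(vo2, 1e-6), vco2_ml_min=np.maximum(vo2, 1e-6) * rer)
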