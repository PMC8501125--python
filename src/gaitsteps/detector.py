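"""Peak-gated step detection on the resultant acceleration.

The detector segments the resultant into *excursions* — maximal runs of
samples above a base threshold — extracts per-excursion peak features
(amplitude, rise and decline time, slope, area above the threshold) and
accepts an excursion as a step only if it clears five gates:

(I)   the excursion exists at all (resultant > ``theta_I``),
(II)  peak amplitude >= ``theta_II``,
(III) rising slope >= ``theta_III``,
(IV)  area above the base threshold >= ``theta_IV``,
(V)   the time gap to the previous *accepted* peak lies within
      ``[theta_V_min, theta_V_max]`` (the first accepted peak is exempt).

Gate (V) is sequential: rejected peaks do not reset the gap reference.  The
lower bound is a refractory period against double-counting heel-strike
ringing; the upper bound encodes "consecutive steps are close in time".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .protocol import ProtocolSegment
from .raw_signal import ResultantSeries, TriaxialRecording, resultant_norm

__all__ = [
    "DetectorParams",
    "PeakFeatures",
    "StepResult",
    "find_excursions",
    "extract_peak_features",
    "gate_steps",
    "count_steps",
]


@dataclass(frozen=True)
class DetectorParams:
    """The five gating thresholds (gate V carries a min and a max).

    Units: ``theta_I``/``theta_II`` in g on the gravity-inclusive resultant,
    ``theta_III`` in g/s, ``theta_IV`` in g*s, the gap bounds in seconds.
    ``theta_II`` below ``theta_I`` is permitted but vacuous, since every
    excursion peak already exceeds ``theta_I``.
    """

    theta_I: float
    theta_II: float
    theta_III: float
    theta_IV: float
    theta_V_max: float
    theta_V_min: float = 0.2

    def __post_init__(self):
        if not self.theta_I > 0:
            raise ValueError("theta_I must be positive")
        if self.theta_III < 0 or self.theta_IV < 0:
            raise ValueError("slope/area thresholds cannot be negative")
        if not self.theta_V_min < self.theta_V_max:
            raise ValueError(
                f"need theta_V_min < theta_V_max, got "
                f"{self.theta_V_min} >= {self.theta_V_max}"
            )

    def to_dict(self) -> dict:
        return {
            "theta_I": self.theta_I,
            "theta_II": self.theta_II,
            "theta_III": self.theta_III,
            "theta_IV": self.theta_IV,
            "theta_V_max": self.theta_V_max,
            "theta_V_min": self.theta_V_min,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorParams":
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class PeakFeatures:
    """Features of one supra-threshold excursion of the resultant."""

    start_t: float
    peak_t: float
    end_t: float
    amplitude: float      # max resultant in the excursion, g
    rise_time: float      # start -> peak, s
    decline_time: float   # peak -> end, s
    slope: float          # (amplitude - theta_I) / rise_time, g/s
    area: float           # trapezoidal integral of (r - theta_I), g*s
    gap_prev: float | None = None  # set during gating, vs previous accepted peak


@dataclass(frozen=True)
class StepResult:
    """Accepted step times plus per-protocol-segment counts."""

    step_times: np.ndarray
    per_segment_counts: dict[ProtocolSegment, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        """Total accepted steps in the recording."""
        return int(len(self.step_times))


def find_excursions(series: ResultantSeries, theta_I: float) -> list[tuple[int, int]]:
    """Maximal runs of samples with r > theta_I, as half-open index pairs."""
    above = series.r > theta_I
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = np.nonzero(edges == 1)[0] + 1
    ends = np.nonzero(edges == -1)[0] + 1
    if above[0]:
        starts = np.concatenate(([0], starts))
    if above[-1]:
        ends = np.concatenate((ends, [len(above)]))
    return list(zip(starts.tolist(), ends.tolist()))


def extract_peak_features(
    series: ResultantSeries, excursion: tuple[int, int], theta_I: float
) -> PeakFeatures:
    """Peak features of one excursion.

    The peak is the argmax of the resultant within the excursion (first
    sample on ties).  Slope is the mean rising slope above the base
    threshold, ``(amplitude - theta_I) / rise_time``; for a peak on the very
    first excursion sample the rise is taken over one sample period.  Area is
    the trapezoidal integral of ``r - theta_I`` across the excursion samples.
    """
    s, e = excursion
    if e <= s:
        raise ValueError("empty excursion")
    r = series.r[s:e]
    k = int(np.argmax(r))
    amplitude = float(r[k])
    start_t = float(series.t[s])
    peak_t = float(series.t[s + k])
    end_t = float(series.t[e - 1])
    rise_time = peak_t - start_t
    decline_time = end_t - peak_t
    if rise_time > 0:
        slope = (amplitude - theta_I) / rise_time
    else:
        slope = (amplitude - theta_I) * series.fs
    area = float(np.trapezoid(r - theta_I, dx=1.0 / series.fs))
    return PeakFeatures(
        start_t=start_t,
        peak_t=peak_t,
        end_t=end_t,
        amplitude=amplitude,
        rise_time=rise_time,
        decline_time=decline_time,
        slope=slope,
        area=area,
    )


def gate_steps(
    features: list[PeakFeatures], params: DetectorParams
) -> list[PeakFeatures]:
    """Apply gates (II)-(V) sequentially; returns accepted features in order.

    The gap gate compares each candidate against the previous *accepted*
    peak, so a rejected candidate neither blocks nor enables its successors
    except through the accepted sequence.
    """
    times = [f.peak_t for f in features]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("features must be ordered by peak time")
    accepted: list[PeakFeatures] = []
    last_t: float | None = None
    for f in features:
        if f.amplitude < params.theta_II:
            continue
        if f.slope < params.theta_III:
            continue
        if f.area < params.theta_IV:
            continue
        if last_t is None:
            accepted.append(replace(f, gap_prev=None))
        else:
            gap = f.peak_t - last_t
            if not (params.theta_V_min <= gap <= params.theta_V_max):
                continue
            accepted.append(replace(f, gap_prev=gap))
        last_t = f.peak_t
    return accepted


def count_steps(
    rec: TriaxialRecording,
    params: DetectorParams,
    segments: list[ProtocolSegment] | tuple[ProtocolSegment, ...] = (),
) -> StepResult:
    """Full pipeline: resultant -> excursions -> features -> gates -> counts.

    Accepted peaks are binned into protocol segments by peak time
    (half-open ``[start_s, end_s)`` intervals).
    """
    segments = list(segments)
    for a, b in zip(segments, segments[1:]):
        if b.start_s < a.end_s:
            raise ValueError(f"segments overlap at t={b.start_s} s")
    if segments:
        t0, t1 = rec.t[0], rec.t[-1]
        if segments[0].start_s < t0 - 1e-9 or segments[-1].end_s > t1 + 1.0 / rec.fs + 1e-9:
            raise ValueError("segments extend beyond the recording span")
    series = resultant_norm(rec)
    feats = [
        extract_peak_features(series, exc, params.theta_I)
        for exc in find_excursions(series, params.theta_I)
    ]
    accepted = gate_steps(feats, params)
    step_times = np.array([f.peak_t for f in accepted])
    counts = {
        seg: int(np.count_nonzero((step_times >= seg.start_s) & (step_times < seg.end_s)))
        for seg in segments
    }
    return StepResult(step_times=step_times, per_segment_counts=counts)
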