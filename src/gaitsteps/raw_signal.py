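"""Raw triaxial recordings, the resultant vector, epoching and MAD.

The detection and energy chains both start from the Euclidean norm of the
three acceleration axes ("resultant"), computed on the raw, gravity-inclusive
signal: a sensor at rest reads close to 1 g on the resultant, and all detector
thresholds are interpreted on that gravity-inclusive scale.  Activity
intensity is summarised per epoch by the mean amplitude deviation (MAD), the
mean absolute deviation of the resultant from its epoch mean, reported in
milli-g because the downstream oxygen-uptake equation consumes mg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TriaxialRecording",
    "ResultantSeries",
    "Epoch",
    "NonUniformSamplingError",
    "resultant_norm",
    "segment_epochs",
    "mad",
]

#: Nominal sensor range in g; samples beyond it trigger a warning, not an error.
SENSOR_RANGE_G = 8.0

#: Maximum deviation of timestamp spacing from 1/fs, in seconds.
UNIFORMITY_TOL_S = 1e-6


class NonUniformSamplingError(ValueError):
    """Raised when timestamps are not uniformly spaced at the claimed rate."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class TriaxialRecording:
    """A uniformly sampled 3-axis acceleration series.

    Parameters
    ----------
    t : array of float
        Sample times in seconds, strictly increasing and uniform at ``1/fs``.
    ax, ay, az : array of float
        Per-axis acceleration in g.
    fs : float
        Sampling rate in Hz.
    """

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    fs: float

    def __post_init__(self):
        t = _as_float_array(self.t, "t")
        ax = _as_float_array(self.ax, "ax")
        ay = _as_float_array(self.ay, "ay")
        az = _as_float_array(self.az, "az")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "ax", ax)
        object.__setattr__(self, "ay", ay)
        object.__setattr__(self, "az", az)
        if len(t) == 0:
            raise ValueError("empty recording")
        if not (len(t) == len(ax) == len(ay) == len(az)):
            raise ValueError(
                "axis/time length mismatch: "
                f"t={len(t)}, ax={len(ax)}, ay={len(ay)}, az={len(az)}"
            )
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        _check_uniform(t, self.fs)
        peak = max(np.abs(ax).max(), np.abs(ay).max(), np.abs(az).max())
        if peak > SENSOR_RANGE_G:
            warnings.warn(
                f"axis value {peak:.3f} g exceeds the nominal ±{SENSOR_RANGE_G:g} g "
                "sensor range; values kept as-is",
                stacklevel=3,
            )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Recording span in seconds (last minus first timestamp)."""
        return float(self.t[-1] - self.t[0])

    @classmethod
    def from_axes(
        cls,
        t,
        ax,
        ay,
        az,
        fs: float | None = None,
        *,
        resample: bool = False,
    ) -> "TriaxialRecording":
        """Build a recording, optionally resampling non-uniform input.

        By default non-uniform timestamps are rejected.  With
        ``resample=True`` the axes are linearly interpolated onto a uniform
        grid at ``fs`` (required in that case) spanning the original times.
        """
        t = _as_float_array(t, "t")
        if len(t) == 0:
            raise ValueError("empty recording")
        if fs is None:
            if len(t) < 2:
                raise ValueError("cannot infer fs from a single sample")
            fs = 1.0 / float(np.median(np.diff(t)))
        if resample:
            tu = t[0] + np.arange(int(np.floor((t[-1] - t[0]) * fs)) + 1) / fs
            ax, ay, az = (np.interp(tu, t, _as_float_array(a, n))
                          for a, n in ((ax, "ax"), (ay, "ay"), (az, "az")))
            t = tu
        return cls(t, ax, ay, az, fs)


def _check_uniform(t: np.ndarray, fs: float) -> None:
    if len(t) < 2:
        return
    dt = np.diff(t)
    bad = np.nonzero(np.abs(dt - 1.0 / fs) > UNIFORMITY_TOL_S)[0]
    if bad.size:
        i = int(bad[0])
        raise NonUniformSamplingError(
            f"non-uniform sampling: gap of {dt[i]:.6g} s between samples "
            f"{i} and {i + 1} (expected {1.0 / fs:.6g} s)"
        )


@dataclass(frozen=True)
class ResultantSeries:
    """Resultant (vector-magnitude) acceleration in g on the source grid."""

    t: np.ndarray
    r: np.ndarray
    fs: float

    def __post_init__(self):
        t = _as_float_array(self.t, "t")
        r = _as_float_array(self.r, "r")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "r", r)
        if len(t) == 0:
            raise ValueError("empty series")
        if len(t) != len(r):
            raise ValueError("t and r length mismatch")
        if np.any(r < 0):
            raise ValueError("resultant magnitude cannot be negative")

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class Epoch:
    """Half-open sample window ``[start_index, end_index)`` of a resultant series."""

    start_index: int
    end_index: int
    values: np.ndarray = field(repr=False)


def resultant_norm(rec: TriaxialRecording) -> ResultantSeries:
    """Euclidean norm of the three axes, sample by sample.

    Gravity is deliberately not removed: the resultant of a still sensor sits
    near 1 g and every downstream threshold assumes that baseline.
    """
    r = np.sqrt(rec.ax**2 + rec.ay**2 + rec.az**2)
    return ResultantSeries(t=rec.t, r=r, fs=rec.fs)


def segment_epochs(series: ResultantSeries, epoch_len: float) -> list[Epoch]:
    """Cut the series into contiguous non-overlapping epochs.

    ``epoch_len`` is in seconds; the trailing partial epoch is dropped, so the
    epochs tile exactly the first ``floor(N / (epoch_len*fs))`` windows.
    """
    n_per = int(round(epoch_len * series.fs))
    if n_per < 1:
        raise ValueError(
            f"epoch of {epoch_len} s is shorter than one sample at {series.fs} Hz"
        )
    n_epochs = len(series) // n_per
    return [
        Epoch(i * n_per, (i + 1) * n_per, series.r[i * n_per : (i + 1) * n_per])
        for i in range(n_epochs)
    ]


def mad(values) -> float:
    """Mean amplitude deviation of a resultant segment, in milli-g.

    MAD = (1/N) * sum_i |r_i - mean(r)| with r in g; the result is scaled by
    1000 because the oxygen-uptake regression consumes MAD in mg.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("mad of empty input")
    return float(np.mean(np.abs(v - v.mean())) * 1000.0)
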