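"""Supervised threshold optimization by exhaustive grid search.

The detector's five gates are tuned on recordings with known per-segment
step counts (video-counted in the lab, simulator-planted here).  Following
the original procedure, "learning" is an exhaustive scan: every point of the
Cartesian product of candidate threshold values is evaluated, the objective
being the mean relative step-count error over all (recording, segment)
pairs, and the argmin is returned.  There is no randomness anywhere.

Default grids are chosen to bracket human gait on a gravity-inclusive
resultant (step frequencies roughly 0.5-3 Hz, peak amplitudes of a waist
sensor between ~1.1 g at a shuffle and several g at a run); they are package
defaults, not values from any study, and are fully overridable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kernels import eval_combo_errors, peak_features_arrays
from .detector import DetectorParams, count_steps
from .protocol import ProtocolSegment
from .raw_signal import TriaxialRecording, resultant_norm

__all__ = [
    "TrainingExample",
    "ParamGrid",
    "GridSearchResult",
    "relative_error",
    "objective",
    "grid_search",
]

#: Axis order used for the flat scan and for lexicographic tie-breaking.
AXIS_ORDER = ("theta_I", "theta_II", "theta_III", "theta_IV", "theta_V_min", "theta_V_max")


@dataclass(frozen=True)
class TrainingExample:
    """A recording plus ground-truth step counts per protocol segment."""

    recording: TriaxialRecording
    segments: tuple[ProtocolSegment, ...]

    def __post_init__(self):
        segs = tuple(self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ValueError("training example needs at least one segment")
        for seg in segs:
            if seg.true_steps is None or seg.true_steps < 1:
                raise ValueError(
                    f"segment at {seg.start_s} s needs true_steps >= 1 for training"
                )


def _axis(name, values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError(f"empty grid axis {name}")
    if np.any(np.diff(arr) < 0):
        raise ValueError(f"grid axis {name} must be sorted ascending")
    return arr


@dataclass(frozen=True)
class ParamGrid:
    """Ordered candidate values for each of the six thresholds."""

    theta_I: np.ndarray
    theta_II: np.ndarray
    theta_III: np.ndarray
    theta_IV: np.ndarray
    theta_V_max: np.ndarray
    theta_V_min: np.ndarray = field(default_factory=lambda: np.array([0.2]))

    def __post_init__(self):
        for name in AXIS_ORDER:
            object.__setattr__(self, name, _axis(name, getattr(self, name)))

    @property
    def n_points(self) -> int:
        return int(np.prod([len(getattr(self, name)) for name in AXIS_ORDER]))

    @classmethod
    def default(cls) -> "ParamGrid":
        """Package-default grids bracketing human cadence and amplitude."""
        return cls(
            theta_I=np.round(np.arange(1.05, 1.60 + 1e-9, 0.05), 10),
            theta_II=np.round(np.arange(1.1, 2.5 + 1e-9, 0.1), 10),
            theta_III=np.arange(0.0, 20.0 + 1e-9, 2.0),
            theta_IV=np.round(np.arange(0.0, 0.4 + 1e-9, 0.05), 10),
            theta_V_max=np.round(np.arange(0.6, 2.0 + 1e-9, 0.2), 10),
            theta_V_min=np.array([0.2]),
        )

    def to_dict(self) -> dict:
        return {name: getattr(self, name).tolist() for name in AXIS_ORDER}

    @classmethod
    def from_dict(cls, d: dict) -> "ParamGrid":
        return cls(**{k: np.asarray(v, dtype=float) for k, v in d.items()})


@dataclass(frozen=True)
class GridSearchResult:
    """Best parameters, their objective, and the full audit table."""

    params: DetectorParams
    objective: float
    table: pd.DataFrame  # one row per grid point, columns AXIS_ORDER + "objective"


def relative_error(detected: int, actual: int) -> float:
    """|detected - actual| / actual."""
    if actual < 1:
        raise ValueError(f"actual step count must be >= 1, got {actual}")
    return abs(detected - actual) / actual


def objective(params: DetectorParams, training: list[TrainingExample]) -> float:
    """Unweighted mean relative error over all (example, segment) pairs."""
    if not training:
        raise ValueError("no training examples")
    errs = []
    for ex in training:
        result = count_steps(ex.recording, params, ex.segments)
        for seg in ex.segments:
            errs.append(relative_error(result.per_segment_counts[seg], seg.true_steps))
    return float(np.mean(errs))


def grid_search(
    grid: ParamGrid, training: list[TrainingExample]
) -> GridSearchResult:
    """Exhaustive scan of the grid's Cartesian product.

    Returns the argmin of :func:`objective`; ties are broken by the earliest
    point in lexicographic scan order over ``AXIS_ORDER``.  The full score
    table (one row per grid point) is returned for audit.

    The scan is organised so that excursion features — which depend only on
    ``theta_I`` — are extracted once per (recording, theta_I), after which a
    compiled kernel sweeps the remaining five axes.
    """
    if not training:
        raise ValueError("no training examples")
    inner_axes = (grid.theta_II, grid.theta_III, grid.theta_IV,
                  grid.theta_V_min, grid.theta_V_max)
    n_inner = int(np.prod([len(a) for a in inner_axes]))
    n_pairs = sum(len(ex.segments) for ex in training)

    resultants = [resultant_norm(ex.recording) for ex in training]
    seg_arrays = []
    for ex in training:
        seg_arrays.append((
            np.array([s.start_s for s in ex.segments]),
            np.array([s.end_s for s in ex.segments]),
            np.array([s.true_steps for s in ex.segments], dtype=np.float64),
        ))

    obj = np.empty(len(grid.theta_I) * n_inner)
    for i1, th1 in enumerate(grid.theta_I):
        err_sum = np.zeros(n_inner)
        for series, (seg_s, seg_e, truth) in zip(resultants, seg_arrays):
            peak_t, amp, slope, area = peak_features_arrays(
                series.r, series.t, series.fs, th1
            )
            eval_combo_errors(
                peak_t, amp, slope, area,
                grid.theta_II, grid.theta_III, grid.theta_IV,
                grid.theta_V_min, grid.theta_V_max,
                seg_s, seg_e, truth, err_sum,
            )
        obj[i1 * n_inner : (i1 + 1) * n_inner] = err_sum / n_pairs

    best_flat = int(np.argmin(obj))  # first minimum == earliest in scan order
    combo = _combo_at(grid, best_flat)
    params = DetectorParams(**combo)
    table = _score_table(grid, obj)
    return GridSearchResult(params=params, objective=float(obj[best_flat]), table=table)


def _combo_at(grid: ParamGrid, flat: int) -> dict:
    sizes = [len(getattr(grid, name)) for name in AXIS_ORDER]
    combo = {}
    for name, size in zip(reversed(AXIS_ORDER), reversed(sizes)):
        combo[name] = float(getattr(grid, name)[flat % size])
        flat //= size
    return combo


def _score_table(grid: ParamGrid, obj: np.ndarray) -> pd.DataFrame:
    axes = [getattr(grid, name) for name in AXIS_ORDER]
    prod = np.array(list(itertools.product(*axes)))
    table = pd.DataFrame(prod, columns=list(AXIS_ORDER))
    table["objective"] = obj
    return table
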