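"""Energy-expenditure estimation and the indirect-calorimetry reference.

Three estimation routes live here:

* the accelerometer chain — per-epoch MAD (mg) -> VO2 (ml·kg⁻¹·min⁻¹) by an
  affine regression -> MET by the standard 1 MET = 3.5 ml·kg⁻¹·min⁻¹;
* two published comparator equations — the ActiGraph adult cut-point
  regression on counts per minute, and the activPAL cadence/duration
  equation in MET·h;
* the indirect-calorimetry reference — per-minute Weir-equation metabolic
  rate from VO2/VCO2, a resting-metabolic-rate rule (mean of the last five
  minutes of a supine plateau, corrected +7% for posture), and protocol
  totals by per-minute summation.

Two printed constants in the source equations are typographically ambiguous;
both readings are implemented and the choice is an explicit argument (see
``sign`` and ``convention`` below).  The defaults take the physiologically
monotone reading.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .protocol import ProtocolSegment
from .raw_signal import ResultantSeries, mad, segment_epochs

__all__ = [
    "EnergyEstimate",
    "EnergySource",
    "ICTrace",
    "RMRResult",
    "vo2_from_mad",
    "met_from_vo2",
    "weir_kcal_day",
    "rmr_from_ic",
    "freedson_met",
    "activpal_met_hours",
    "total_ee_protocol",
    "met_per_segment",
]

#: 1 MET in oxygen-uptake units, ml O2 per kg per minute.
ML_O2_PER_KG_MIN_PER_MET = 3.5

#: Supine-to-upright correction applied to resting metabolic rate.
RMR_POSTURE_FACTOR = 1.07

#: Physiologic plausibility band for the respiratory exchange ratio at rest.
RER_RANGE = (0.7, 0.99)


class EnergySource(str, Enum):
    MAD_CHAIN = "mad_chain"
    FREEDSON = "freedson"
    ACTIVPAL = "activpal"
    INDIRECT_CALORIMETRY = "indirect_calorimetry"


@dataclass(frozen=True)
class EnergyEstimate:
    """One VO2/MET (and optionally kcal) estimate with its provenance."""

    vo2: float            # ml·kg⁻¹·min⁻¹
    met: float
    source: EnergySource
    kcal: float | None = None


@dataclass(frozen=True)
class ICTrace:
    """Per-minute indirect-calorimetry trace, VO2 and VCO2 in ml/min."""

    vo2_ml_min: np.ndarray
    vco2_ml_min: np.ndarray

    def __post_init__(self):
        vo2 = np.asarray(self.vo2_ml_min, dtype=float)
        vco2 = np.asarray(self.vco2_ml_min, dtype=float)
        object.__setattr__(self, "vo2_ml_min", vo2)
        object.__setattr__(self, "vco2_ml_min", vco2)
        if vo2.shape != vco2.shape or vo2.ndim != 1:
            raise ValueError("VO2 and VCO2 must be equal-length 1-d series")
        if vo2.size == 0:
            raise ValueError("empty trace")
        if np.any(vo2 <= 0) or np.any(vco2 <= 0):
            raise ValueError("VO2/VCO2 must be positive")

    def __len__(self) -> int:
        return len(self.vo2_ml_min)

    @property
    def rer(self) -> np.ndarray:
        """Respiratory exchange ratio, VCO2/VO2, per minute."""
        return self.vco2_ml_min / self.vo2_ml_min


@dataclass(frozen=True)
class RMRResult:
    """Resting metabolic rate from the last five minutes of a supine trace."""

    rmr_kcal_day: float       # posture-corrected (x 1.07)
    raw_rmr_kcal_day: float
    rer_flags: tuple[int, ...]  # minute indices with RER outside RER_RANGE


def vo2_from_mad(mad_mg: float, *, sign: str = "plus") -> float:
    """Oxygen uptake (ml·kg⁻¹·min⁻¹) from MAD in mg: ``7.920 ± 0.0331*MAD``.

    The source regression is printed with an ambiguous dash.  ``sign="plus"``
    (default) makes VO2 increase with activity, consistent with the MAD
    methodology the regression derives from; ``sign="minus"`` is the literal
    reading.
    """
    if mad_mg < 0:
        raise ValueError("MAD cannot be negative")
    if sign == "plus":
        return 7.920 + 0.0331 * mad_mg
    if sign == "minus":
        return 7.920 - 0.0331 * mad_mg
    raise ValueError(f"sign must be 'plus' or 'minus', got {sign!r}")


def met_from_vo2(vo2: float) -> float:
    """Standard MET conversion, VO2 / 3.5."""
    if vo2 < 0:
        raise ValueError("VO2 cannot be negative")
    return vo2 / ML_O2_PER_KG_MIN_PER_MET


def weir_kcal_day(vo2_ml_min: float, vco2_ml_min: float) -> float:
    """Weir metabolic rate in kcal/day: ``1.44 * (3.94*VO2 + 1.11*VCO2)``.

    Inputs are in ml/min (not L/min — a 70 kg adult at rest is ~250 ml/min).
    """
    if vo2_ml_min < 0 or vco2_ml_min < 0:
        raise ValueError("gas-exchange inputs cannot be negative")
    return 1.44 * (3.94 * vo2_ml_min + 1.11 * vco2_ml_min)


def rmr_from_ic(trace: ICTrace) -> RMRResult:
    """RMR from the final 5 minutes of a supine plateau trace.

    Raw RMR is the Weir rate of the mean VO2/VCO2 over the last five
    minutes; the corrected value multiplies by 1.07 for posture.  Minutes
    anywhere in the trace with RER outside [0.7, 0.99] are flagged, not
    rejected.
    """
    if len(trace) < 5:
        raise ValueError(f"need at least 5 minutes for RMR, got {len(trace)}")
    vo2 = float(trace.vo2_ml_min[-5:].mean())
    vco2 = float(trace.vco2_ml_min[-5:].mean())
    raw = weir_kcal_day(vo2, vco2)
    rer = trace.rer
    flags = tuple(int(i) for i in np.nonzero((rer < RER_RANGE[0]) | (rer > RER_RANGE[1]))[0])
    return RMRResult(
        rmr_kcal_day=RMR_POSTURE_FACTOR * raw,
        raw_rmr_kcal_day=raw,
        rer_flags=flags,
    )


def freedson_met(cpm: float) -> float:
    """ActiGraph adult cut-point regression: MET = 1.439008 + 0.000795 * CPM."""
    if cpm < 0:
        raise ValueError("counts per minute cannot be negative")
    return 1.439008 + 0.000795 * cpm


def activpal_met_hours(
    cadence: float, duration_h: float, *, convention: str = "corrected"
) -> float:
    """activPAL energy equation, MET·h from cadence (steps/min) and hours.

    ``MET·h = 1.4*d + K * (c/120) * d``.  The source prints the constant as
    "(4–14)", which read literally gives negative energy; the default
    ``convention="corrected"`` uses K = 4 − 1.4 = 2.6 (the published activPAL
    moderate-to-vigorous constant pattern), ``convention="literal"`` uses
    K = 4 − 14 = −10.
    """
    if cadence < 0 or duration_h < 0:
        raise ValueError("cadence and duration cannot be negative")
    if convention == "corrected":
        k = 4.0 - 1.4
    elif convention == "literal":
        k = 4.0 - 14.0
    else:
        raise ValueError(f"convention must be 'corrected' or 'literal', got {convention!r}")
    return 1.4 * duration_h + k * (cadence / 120.0) * duration_h


def total_ee_protocol(trace: ICTrace) -> float:
    """Total protocol energy in kcal: per-minute Weir rates summed.

    Each minute contributes its kcal/day rate divided by 1440 min/day.
    """
    per_min = [
        weir_kcal_day(v, c) / 1440.0
        for v, c in zip(trace.vo2_ml_min, trace.vco2_ml_min)
    ]
    return float(np.sum(per_min))


def met_per_segment(
    series: ResultantSeries,
    segments: list[ProtocolSegment] | tuple[ProtocolSegment, ...],
    epoch_len: float = 6.0,
    *,
    sign: str = "plus",
) -> dict[ProtocolSegment, float]:
    """Mean MET per protocol segment via the MAD chain.

    The series is cut into fixed epochs (default 6 s); each epoch's MAD feeds
    the VO2 regression and the MET conversion, and epochs are assigned to the
    segment containing their start time.
    """
    epochs = segment_epochs(series, epoch_len)
    out: dict[ProtocolSegment, float] = {}
    starts = np.array([series.t[e.start_index] for e in epochs])
    for seg in segments:
        idx = np.nonzero((starts >= seg.start_s) & (starts < seg.end_s))[0]
        if idx.size == 0:
            raise ValueError(
                f"segment [{seg.start_s}, {seg.end_s}) s holds no complete "
                f"{epoch_len} s epoch"
            )
        mets = [
            met_from_vo2(vo2_from_mad(mad(epochs[i].values), sign=sign)) for i in idx
        ]
        out[seg] = float(np.mean(mets))
    return out
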