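"""Method-agreement statistics for device-vs-reference comparisons.

The battery applied to each device/speed cell: mean absolute percentage
error (MAPE, with the ±sd of the per-subject percentages), a paired t test
with the 95% CI of the mean difference, an intraclass correlation with its
F test and 95% CI, Bland–Altman limits of agreement, and the R² of an
ordinary least-squares fit of estimated on actual.  A MAPE above 5% is
flagged as relevant disagreement.

ICC defaults to the two-way random-effects, absolute-agreement,
single-measure form (ICC(2,1)) — the standard choice when both methods are
to be interchangeable; the consistency form ICC(3,1) is available via
``model=``.  Negative ICC estimates are possible and are reported as-is with
category "low".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedSample",
    "MapeResult",
    "PairedTResult",
    "IccResult",
    "BlandAltmanResult",
    "AgreementReport",
    "mape",
    "paired_t",
    "icc",
    "classify_icc",
    "bland_altman",
    "regression_r2",
    "evaluate_device",
    "MAPE_DISAGREEMENT_PCT",
]

#: MAPE above this many percent counts as relevant disagreement.
MAPE_DISAGREEMENT_PCT = 5.0


@dataclass(frozen=True)
class PairedSample:
    """Actual (reference) and estimated (device) values, pairwise."""

    actual: np.ndarray
    estimated: np.ndarray
    labels: tuple | None = None

    def __post_init__(self):
        a = np.asarray(self.actual, dtype=float)
        e = np.asarray(self.estimated, dtype=float)
        object.__setattr__(self, "actual", a)
        object.__setattr__(self, "estimated", e)
        if a.shape != e.shape or a.ndim != 1:
            raise ValueError("actual and estimated must be equal-length 1-d vectors")
        if a.size == 0:
            raise ValueError("empty sample")

    def __len__(self) -> int:
        return len(self.actual)

    @property
    def differences(self) -> np.ndarray:
        """Estimated minus actual, pairwise."""
        return self.estimated - self.actual


@dataclass(frozen=True)
class MapeResult:
    mean_pct: float
    sd_pct: float
    flagged: bool  # mean above the 5% relevant-disagreement bound


@dataclass(frozen=True)
class PairedTResult:
    mean_diff: float
    sd_diff: float
    ci95: tuple[float, float]
    t: float
    p: float
    df: int
    degenerate: bool = False  # zero-variance differences: t/p undefined


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci95: tuple[float, float]
    f: float
    p: float
    category: str


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    loa_low: float
    loa_high: float
    pair_means: np.ndarray
    pair_diffs: np.ndarray


@dataclass(frozen=True)
class AgreementReport:
    """One comparison cell (e.g. one speed, or the protocol total)."""

    label: str
    n: int
    mape: MapeResult
    t_test: PairedTResult
    icc: IccResult | None       # None when n < 3 (inestimable)
    bland_altman: BlandAltmanResult
    r_squared: float | None     # None when n < 3 or actual is constant


def mape(sample: PairedSample) -> MapeResult:
    """Mean absolute percentage error: mean of |A−F|/A × 100, with its sd.

    The sd is the sample sd (ddof=1) of the per-pair absolute percentage
    errors; it is NaN for a single pair.
    """
    a, f = sample.actual, sample.estimated
    if np.any(a <= 0):
        raise ValueError("MAPE requires all actual values to be positive")
    pct = np.abs((a - f) / a) * 100.0
    mean = float(pct.mean())
    sd = float(pct.std(ddof=1)) if len(pct) > 1 else float("nan")
    return MapeResult(mean_pct=mean, sd_pct=sd, flagged=mean > MAPE_DISAGREEMENT_PCT)


def paired_t(sample: PairedSample) -> PairedTResult:
    """Classical paired t test on estimated − actual, two-sided, with 95% CI."""
    d = sample.differences
    n = len(d)
    if n < 2:
        raise ValueError("paired t test needs at least 2 pairs")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0:
        return PairedTResult(mean, 0.0, (mean, mean), float("nan"), float("nan"),
                             df, degenerate=True)
    se = sd / np.sqrt(n)
    t = mean / se
    p = 2.0 * stats.t.sf(abs(t), df)
    half = stats.t.ppf(0.975, df) * se
    return PairedTResult(mean, sd, (mean - half, mean + half), float(t), float(p), df)


def icc(sample: PairedSample, *, model: str = "ICC2") -> IccResult:
    """Intraclass correlation of the two methods, with F test and 95% CI.

    ``model="ICC2"`` (default) is two-way random effects, absolute
    agreement, single measures; ``"ICC3"`` is the two-way mixed consistency
    form.  Derived from the two-way ANOVA decomposition with subjects as
    rows and the two methods as raters.
    """
    a, e = sample.actual, sample.estimated
    n = len(a)
    if n < 3:
        raise ValueError("ICC needs at least 3 paired ratings")
    if np.ptp((a + e) / 2) == 0:
        raise ValueError("degenerate ANOVA: no between-subject variance in ratings")
    x = np.column_stack([a, e])
    k = 2
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = max(sst - ssr - ssc, 0.0)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    alpha = 0.05
    df1, df2 = n - 1, (n - 1) * (k - 1)
    if mse == 0 and msc == 0:
        # perfect agreement: all variance is between subjects
        return IccResult(icc=1.0, ci95=(1.0, 1.0), f=float("inf"), p=0.0,
                         category=classify_icc(1.0))
    if model == "ICC2":
        value = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
        fval = msr / mse if mse > 0 else float("inf")
        p = float(stats.f.sf(fval, df1, df2)) if np.isfinite(fval) else 0.0
        # Satterthwaite CI for the absolute-agreement form (McGraw & Wong)
        r = min(float(value), 1.0 - 1e-12)
        ca = k * r / (n * (1.0 - r))
        cb = 1.0 + k * r * (n - 1) / (n * (1.0 - r))
        v = (ca * msc + cb * mse) ** 2 / (
            (ca * msc) ** 2 / (k - 1) + (cb * mse) ** 2 / ((n - 1) * (k - 1)))
        f2u = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f2l = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f2u * mse) / (
            f2u * (k * msc + (k * n - k - n) * mse) + n * msr)
        hi = n * (f2l * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f2l * msr)
    elif model == "ICC3":
        value = (msr - mse) / (msr + (k - 1) * mse)
        fval = msr / mse if mse > 0 else float("inf")
        p = float(stats.f.sf(fval, df1, df2)) if np.isfinite(fval) else 0.0
        fl = fval / stats.f.ppf(1 - alpha / 2, df1, df2)
        fu = fval * stats.f.ppf(1 - alpha / 2, df2, df1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
    else:
        raise ValueError(f"model must be 'ICC2' or 'ICC3', got {model!r}")
    return IccResult(
        icc=float(value),
        ci95=(float(lo), float(hi)),
        f=float(fval),
        p=p,
        category=classify_icc(min(float(value), 1.0)),
    )


def classify_icc(value: float) -> str:
    """Band an ICC estimate: >0.90 excellent, (0.75, 0.90] good,
    [0.60, 0.75] moderate, <0.60 low (negative estimates are low)."""
    if value > 1:
        raise ValueError(f"ICC cannot exceed 1, got {value}")
    if value > 0.90:
        return "excellent"
    if value > 0.75:
        return "good"
    if value >= 0.60:
        return "moderate"
    return "low"


def bland_altman(sample: PairedSample) -> BlandAltmanResult:
    """Mean difference and 95% limits of agreement (mean ± 1.96 sd)."""
    if len(sample) < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = sample.differences
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        mean_diff=mean,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
        pair_means=(sample.actual + sample.estimated) / 2.0,
        pair_diffs=d,
    )


def regression_r2(sample: PairedSample) -> float:
    """R² of the OLS fit of estimated on actual."""
    if len(sample) < 3:
        raise ValueError("regression needs at least 3 pairs")
    if np.ptp(sample.actual) == 0:
        raise ValueError("zero variance in actual values")
    res = stats.linregress(sample.actual, sample.estimated)
    return float(res.rvalue**2)


def evaluate_device(
    actual_by_label: dict, estimated_by_label: dict, *, icc_model: str = "ICC2"
) -> list[AgreementReport]:
    """Run the full battery per label (speed) plus a pooled "total" row.

    ``actual_by_label``/``estimated_by_label`` map a label (e.g. speed in
    km/h) to equal-length per-subject vectors.  The total row sums each
    subject's values across labels, mirroring a per-protocol step total.
    """
    if set(actual_by_label) != set(estimated_by_label):
        missing = set(actual_by_label) ^ set(estimated_by_label)
        raise ValueError(f"label mismatch between actual and estimated: {missing}")
    reports = []
    labels = list(actual_by_label)
    for label in labels:
        sample = PairedSample(actual_by_label[label], estimated_by_label[label])
        reports.append(_report(str(label), sample, icc_model))
    total = PairedSample(
        np.sum([np.asarray(actual_by_label[k], dtype=float) for k in labels], axis=0),
        np.sum([np.asarray(estimated_by_label[k], dtype=float) for k in labels], axis=0),
    )
    reports.append(_report("total", total, icc_model))
    return reports


def _report(label: str, sample: PairedSample, icc_model: str) -> AgreementReport:
    try:
        r2 = regression_r2(sample)
    except ValueError:
        r2 = None
    try:
        icc_res = icc(sample, model=icc_model)
    except ValueError:
        icc_res = None
    return AgreementReport(
        label=label,
        n=len(sample),
        mape=mape(sample),
        t_test=paired_t(sample),
        icc=icc_res,
        bland_altman=bland_altman(sample),
        r_squared=r2,
    )


def reports_to_frame(reports: list[AgreementReport]) -> pd.DataFrame:
    """Flatten reports into the customary table layout (one row per label)."""
    rows = []
    for r in reports:
        rows.append({
            "label": r.label,
            "n": r.n,
            "mape_pct": r.mape.mean_pct,
            "mape_sd": r.mape.sd_pct,
            "mape_flag": r.mape.flagged,
            "mean_diff": r.t_test.mean_diff,
            "sd_diff": r.t_test.sd_diff,
            "ci95_low": r.t_test.ci95[0],
            "ci95_high": r.t_test.ci95[1],
            "t_p": r.t_test.p,
            "icc": r.icc.icc if r.icc else None,
            "icc_ci_low": r.icc.ci95[0] if r.icc else None,
            "icc_ci_high": r.icc.ci95[1] if r.icc else None,
            "icc_F": r.icc.f if r.icc else None,
            "icc_F_p": r.icc.p if r.icc else None,
            "icc_category": r.icc.category if r.icc else None,
            "ba_mean_diff": r.bland_altman.mean_diff,
            "ba_loa_low": r.bland_altman.loa_low,
            "ba_loa_high": r.bland_altman.loa_high,
            "r_squared": r.r_squared,
        })
    return pd.DataFrame(rows)
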