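"""Numba kernels for the exhaustive threshold search.

The public detector (:mod:`gaitsteps.detector`) is the readable reference
path.  The grid search must gate hundreds of thousands of threshold
combinations against thousands of candidate peaks per recording, so the hot
loops live here as nopython kernels operating on plain float arrays.  The
feature definitions are identical to :func:`detector.extract_peak_features`
and the test suite asserts the two routes agree.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["peak_features_arrays", "eval_combo_errors", "count_accepted"]


@njit(cache=True)
def _features_pass(r, t, fs, theta_I, peak_t, amp, slope, area):  # pragma: no cover
    n = r.shape[0]
    m = 0
    i = 0
    while i < n:
        if r[i] > theta_I:
            s = i
            j = i
            kmax = s
            rmax = r[s]
            while j + 1 < n and r[j + 1] > theta_I:
                j += 1
                if r[j] > rmax:
                    rmax = r[j]
                    kmax = j
            # excursion samples are [s, j]
            a = 0.0
            for k in range(s, j):
                a += 0.5 * ((r[k] - theta_I) + (r[k + 1] - theta_I))
            a /= fs
            rise = t[kmax] - t[s]
            if rise > 0.0:
                sl = (rmax - theta_I) / rise
            else:
                sl = (rmax - theta_I) * fs
            peak_t[m] = t[kmax]
            amp[m] = rmax
            slope[m] = sl
            area[m] = a
            m += 1
            i = j + 1
        else:
            i += 1
    return m


def peak_features_arrays(r: np.ndarray, t: np.ndarray, fs: float, theta_I: float):
    """Single-pass excursion features as parallel arrays (peak_t, amp, slope, area)."""
    cap = r.shape[0] // 2 + 1
    peak_t = np.empty(cap)
    amp = np.empty(cap)
    slope = np.empty(cap)
    area = np.empty(cap)
    m = _features_pass(
        np.ascontiguousarray(r, dtype=np.float64),
        np.ascontiguousarray(t, dtype=np.float64),
        float(fs), float(theta_I), peak_t, amp, slope, area,
    )
    return peak_t[:m].copy(), amp[:m].copy(), slope[:m].copy(), area[:m].copy()


@njit(cache=True)
def count_accepted(
    peak_t, amp, slope, area,
    th2, th3, th4, tvmin, tvmax,
    seg_start, seg_end, counts,
):  # pragma: no cover
    """Sequential gate for one threshold combination; fills per-segment counts."""
    counts[:] = 0
    last_t = -1.0
    have_last = False
    p = 0
    nseg = seg_start.shape[0]
    for i in range(peak_t.shape[0]):
        if amp[i] < th2 or slope[i] < th3 or area[i] < th4:
            continue
        if have_last:
            gap = peak_t[i] - last_t
            if gap < tvmin or gap > tvmax:
                continue
        last_t = peak_t[i]
        have_last = True
        while p < nseg and peak_t[i] >= seg_end[p]:
            p += 1
        if p < nseg and peak_t[i] >= seg_start[p]:
            counts[p] += 1


@njit(cache=True)
def eval_combo_errors(
    peak_t, amp, slope, area,
    th2s, th3s, th4s, tvmins, tvmaxs,
    seg_start, seg_end, true_steps,
    err_sum,
):  # pragma: no cover
    """Accumulate sum of per-segment relative errors into ``err_sum``.

    ``err_sum`` is indexed by the flat combination index in nested scan order
    (theta_II, theta_III, theta_IV, theta_V_min, theta_V_max), matching the
    optimizer's lexicographic ordering within one theta_I slice.
    """
    nseg = seg_start.shape[0]
    counts = np.zeros(nseg, dtype=np.int64)
    c = 0
    for i2 in range(th2s.shape[0]):
        for i3 in range(th3s.shape[0]):
            for i4 in range(th4s.shape[0]):
                for i5 in range(tvmins.shape[0]):
                    for i6 in range(tvmaxs.shape[0]):
                        count_accepted(
                            peak_t, amp, slope, area,
                            th2s[i2], th3s[i3], th4s[i4],
                            tvmins[i5], tvmaxs[i6],
                            seg_start, seg_end, counts,
                        )
                        e = 0.0
                        for s in range(nseg):
                            d = counts[s] - true_steps[s]
                            if d < 0:
                                d = -d
                            e += d / true_steps[s]
                        err_sum[c] += e
                        c += 1
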