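"""Excursion finding, peak features and the five-gate step acceptance."""

import dataclasses

import numpy as np
import pytest

from gaitsteps import (
    DetectorParams,
    PeakFeatures,
    ProtocolSegment,
    ResultantSeries,
    count_steps,
    extract_peak_features,
    find_excursions,
    gate_steps,
    resultant_norm,
)
from gaitsteps.simulate import GaitSimConfig, simulate_recording

from conftest import make_pulse_series, random_recording

WIDE_OPEN = DetectorParams(theta_I=1.3, theta_II=1.3, theta_III=0.0,
                           theta_IV=0.0, theta_V_max=100.0, theta_V_min=0.0001)


def triangle_series(peak=2.0, base=1.0, rise_s=0.5, fs=100.0):
    """One symmetric triangular pulse from base up to `peak` and back."""
    up = np.linspace(base, peak, int(rise_s * fs) + 1)
    r = np.concatenate([np.full(100, base), up, up[-2::-1], np.full(100, base)])
    t = np.arange(len(r)) / fs
    return ResultantSeries(t=t, r=r, fs=fs)


class TestFindExcursions:
    def test_subthreshold_series_empty(self, flat_series):
        assert find_excursions(flat_series, 1.3) == []

    def test_triangle_boundaries_match_analytic_crossings(self):
        series = triangle_series(peak=2.0, base=1.0, rise_s=0.5)
        # ramp r(i) = 1 + (i-100)*0.02 for i in [100, 150]; r > 1.3 from i=116
        excs = find_excursions(series, 1.3)
        assert len(excs) == 1
        s, e = excs[0]
        assert series.r[s] > 1.3 and series.r[s - 1] <= 1.3
        assert series.r[e - 1] > 1.3 and series.r[e] <= 1.3
        assert s == 116 and e == 185

    def test_two_pulses_with_subthreshold_valley(self):
        series = make_pulse_series([(1.0, 1.0), (2.0, 1.0)], duration=3.0)
        assert len(find_excursions(series, 1.3)) == 2

    def test_excursions_ordered_non_overlapping(self, rng):
        series = resultant_norm(random_recording(rng))
        excs = find_excursions(series, 1.2)
        flat = [i for s, e in excs for i in (s, e)]
        assert flat == sorted(flat)


class TestPeakFeatures:
    def test_symmetric_triangle_rise_equals_decline(self):
        series = triangle_series()
        f = extract_peak_features(series, find_excursions(series, 1.3)[0], 1.3)
        assert f.rise_time == pytest.approx(f.decline_time, abs=1 / series.fs)

    def test_amplitude_is_max_readoff(self):
        series = triangle_series(peak=2.0)
        f = extract_peak_features(series, find_excursions(series, 1.3)[0], 1.3)
        assert f.amplitude == pytest.approx(2.0)
        assert f.start_t <= f.peak_t <= f.end_t

    def test_area_matches_oversampled_rectangle_oracle(self, rng):
        # random smooth pulse, area above threshold vs 10x-oversampled sum
        amp, sigma, fs, th = 1.4, 0.06, 100.0, 1.25

        def r_of(t):
            return 1.0 + amp * np.exp(-0.5 * ((t - 1.0) / sigma) ** 2)

        t = np.arange(200) / fs
        series = ResultantSeries(t=t, r=r_of(t), fs=fs)
        (exc,) = find_excursions(series, th)
        f = extract_peak_features(series, exc, th)
        tf = np.arange(2000) / (10 * fs)
        fine = r_of(tf) - th
        oracle = np.sum(fine[fine > 0]) / (10 * fs)
        assert f.area == pytest.approx(oracle, rel=0.02)

    def test_single_sample_excursion_slope_over_one_period(self):
        r = np.ones(10)
        r[5] = 2.0
        series = ResultantSeries(np.arange(10) / 100, r, 100.0)
        (exc,) = find_excursions(series, 1.3)
        f = extract_peak_features(series, exc, 1.3)
        assert f.rise_time == 0.0
        assert f.slope == pytest.approx((2.0 - 1.3) * 100.0)

    def test_empty_excursion_rejected(self, flat_series):
        with pytest.raises(ValueError, match="empty"):
            extract_peak_features(flat_series, (5, 5), 1.3)

    def test_tie_at_peak_first_sample_wins(self):
        r = np.ones(10)
        r[4] = r[6] = 2.0
        r[5] = 2.0
        series = ResultantSeries(np.arange(10) / 100, r, 100.0)
        (exc,) = find_excursions(series, 1.3)
        f = extract_peak_features(series, exc, 1.3)
        assert f.peak_t == pytest.approx(series.t[4])


def feat(peak_t, amplitude=2.0, slope=10.0, area=0.1):
    return PeakFeatures(start_t=peak_t - 0.05, peak_t=peak_t, end_t=peak_t + 0.05,
                        amplitude=amplitude, rise_time=0.05, decline_time=0.05,
                        slope=slope, area=area)


class TestGateSteps:
    def test_wide_open_gates_accept_all(self):
        feats = [feat(t) for t in np.arange(10) * 0.5]
        assert len(gate_steps(feats, WIDE_OPEN)) == 10

    def test_amplitude_gate_rejects_everything(self):
        feats = [feat(t) for t in np.arange(10) * 0.5]
        params = dataclasses.replace(WIDE_OPEN, theta_II=10.0)
        assert gate_steps(feats, params) == []

    def test_sequential_refractory_hand_trace(self):
        # peaks 0.1 s apart, refractory 0.2 s: middle rejected, gap to the
        # third is then 0.2 s from the FIRST accepted peak -> accepted
        feats = [feat(0.0), feat(0.1), feat(0.2)]
        params = DetectorParams(theta_I=1.3, theta_II=1.3, theta_III=0.0,
                                theta_IV=0.0, theta_V_max=2.0, theta_V_min=0.2)
        accepted = gate_steps(feats, params)
        assert [f.peak_t for f in accepted] == [0.0, 0.2]

    def test_gap_longer_than_max_rejected(self):
        feats = [feat(0.0), feat(5.0)]
        params = dataclasses.replace(WIDE_OPEN, theta_V_max=2.0)
        assert [f.peak_t for f in gate_steps(feats, params)] == [0.0]

    def test_gap_prev_recorded_against_accepted_only(self):
        feats = [feat(0.0), feat(0.1), feat(0.5)]
        params = DetectorParams(theta_I=1.3, theta_II=1.3, theta_III=0.0,
                                theta_IV=0.0, theta_V_max=2.0, theta_V_min=0.2)
        accepted = gate_steps(feats, params)
        assert accepted[0].gap_prev is None
        assert accepted[1].gap_prev == pytest.approx(0.5)

    def test_unordered_features_rejected(self):
        with pytest.raises(ValueError, match="ordered"):
            gate_steps([feat(1.0), feat(0.5)], WIDE_OPEN)


def reference_count(rec, params, segments):
    """Independent single-pass implementation of the whole detection rule."""
    r = np.sqrt(rec.ax**2 + rec.ay**2 + rec.az**2)
    accepted = []
    last = None
    i = 0
    n = len(r)
    while i < n:
        if r[i] <= params.theta_I:
            i += 1
            continue
        j = i
        while j + 1 < n and r[j + 1] > params.theta_I:
            j += 1
        seg = r[i : j + 1]
        k = int(np.argmax(seg))
        amp = seg[k]
        rise = k / rec.fs
        slope = (amp - params.theta_I) / rise if rise > 0 else (amp - params.theta_I) * rec.fs
        area = np.trapezoid(seg - params.theta_I, dx=1.0 / rec.fs)
        pt = rec.t[i + k]
        ok = amp >= params.theta_II and slope >= params.theta_III and area >= params.theta_IV
        if ok and last is not None:
            ok = params.theta_V_min <= pt - last <= params.theta_V_max
        if ok:
            accepted.append(pt)
            last = pt
        i = j + 1
    counts = {
        seg: sum(1 for p in accepted if seg.start_s <= p < seg.end_s)
        for seg in segments
    }
    return counts, len(accepted)


class TestCountSteps:
    def test_planted_impulses_recovered_exactly(self, quiet_config):
        from gaitsteps import ProtocolSpec

        protocol = ProtocolSpec.from_speeds([4.5], segment_duration_s=60.0)
        subj = simulate_recording(quiet_config, protocol, seed=3)
        params = DetectorParams(theta_I=1.2, theta_II=1.3, theta_III=0.0,
                                theta_IV=0.0, theta_V_max=2.0)
        result = count_steps(subj.recording, params, subj.segments)
        (seg,) = subj.segments
        assert result.per_segment_counts[seg] == seg.true_steps
        assert result.total == seg.true_steps

    def test_absurd_amplitude_threshold_counts_zero(self, noisy_subject):
        params = DetectorParams(theta_I=1.2, theta_II=10.0, theta_III=0.0,
                                theta_IV=0.0, theta_V_max=2.0)
        assert count_steps(noisy_subject.recording, params, noisy_subject.segments).total == 0

    def test_matches_independent_reference_on_noisy_recordings(self, rng):
        params = DetectorParams(theta_I=1.15, theta_II=1.3, theta_III=2.0,
                                theta_IV=0.005, theta_V_max=1.5, theta_V_min=0.2)
        for _ in range(5):
            rec = random_recording(rng)
            segments = (ProtocolSegment(3.0, 0.0, 5.0), ProtocolSegment(4.5, 5.0, 10.0))
            result = count_steps(rec, params, segments)
            ref_counts, ref_total = reference_count(rec, params, segments)
            assert result.total == ref_total
            assert {s: result.per_segment_counts[s] for s in segments} == ref_counts

    def test_overlapping_segments_rejected(self, noisy_subject):
        segs = (ProtocolSegment(3.0, 0.0, 60.0), ProtocolSegment(4.5, 50.0, 100.0))
        with pytest.raises(ValueError, match="overlap"):
            count_steps(noisy_subject.recording, WIDE_OPEN, segs)

    def test_deterministic(self, noisy_subject):
        params = DetectorParams(theta_I=1.2, theta_II=1.4, theta_III=0.0,
                                theta_IV=0.0, theta_V_max=1.5)
        a = count_steps(noisy_subject.recording, params, noisy_subject.segments)
        b = count_steps(noisy_subject.recording, params, noisy_subject.segments)
        assert a.total == b.total
        np.testing.assert_array_equal(a.step_times, b.step_times)


class TestMonotonicity:
    """Tightening any minimum gate cannot increase the count (a theorem when
    the sequential gap gate is non-binding); widening the gap window cannot
    decrease it on gait-like signals with regular inter-step gaps."""

    base = DetectorParams(theta_I=1.15, theta_II=1.25, theta_III=2.0,
                          theta_IV=0.002, theta_V_max=100.0, theta_V_min=1e-4)

    @pytest.mark.parametrize("axis, values", [
        ("theta_I", [1.05, 1.15, 1.3, 1.5]),
        ("theta_II", [1.2, 1.4, 1.7, 2.2]),
        ("theta_III", [0.0, 4.0, 10.0, 18.0]),
        ("theta_IV", [0.0, 0.005, 0.02, 0.1]),
    ])
    def test_count_non_increasing_in_min_thresholds(self, axis, values, rng):
        # when theta_I itself moves, the slope/area features move with it;
        # the ordering is exact with the downstream gates open
        base = (dataclasses.replace(self.base, theta_III=0.0, theta_IV=0.0)
                if axis == "theta_I" else self.base)
        for _ in range(5):
            rec = random_recording(rng)
            counts = [
                count_steps(rec, dataclasses.replace(base, **{axis: v})).total
                for v in values
            ]
            assert counts == sorted(counts, reverse=True)

    def test_count_non_decreasing_in_gap_max(self):
        from gaitsteps import GaitSimConfig, ProtocolSpec, simulate_recording

        gate = dataclasses.replace(self.base, theta_V_min=0.2)
        for seed in range(5):
            subj = simulate_recording(GaitSimConfig(),
                                      ProtocolSpec.from_speeds([4.5], 30.0), seed)
            counts = [
                count_steps(subj.recording,
                            dataclasses.replace(gate, theta_V_max=v)).total
                for v in [0.4, 0.8, 1.5, 3.0]
            ]
            assert counts == sorted(counts)
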