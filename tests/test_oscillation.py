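import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bzkymo.oscillation import (
    IntensityTrace,
    analyze_trace,
    detect_peaks,
    estimate_period,
    instantaneous_frequency,
    low_median,
    lowpass,
    peak_area,
    segment_periods,
    subtract_baseline,
    summarize_features,
)
from bzkymo.synth import LifecycleSchedule, NoiseConfig, simulate_traces
from oracles import brute_autocorr_period


class TestLowpass:
    def test_constant_unchanged(self):
        x = np.full(50, 3.14)
        np.testing.assert_allclose(lowpass(x, 9), x)

    def test_slow_sinusoid_attenuated_below_one_percent(self):
        t = np.arange(400.0)
        x = np.sin(2 * np.pi * t / 200.0)
        y = lowpass(x, 5)
        assert y[100:-100].max() > 0.99 * x.max()

    def test_nyquist_attenuated_above_ninety_percent(self):
        x = np.array([1.0, -1.0] * 100)
        y = lowpass(x, 11)
        assert np.abs(y[20:-20]).max() < 0.1

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError):
            lowpass(np.array([1.0, 2.0]), 3)


class TestEstimatePeriod:
    def test_sinusoid_period_recovered_within_one_sample(self):
        t = np.arange(0, 500, 2.5)
        assert estimate_period(np.sin(2 * np.pi * t / 25), 2.5) == pytest.approx(
            25.0, abs=2.5
        )

    def test_constant_has_no_period(self):
        assert estimate_period(np.ones(100), 2.5) is None

    def test_dominant_component_wins(self):
        t = np.arange(0, 500, 2.5)
        x = 3 * np.sin(2 * np.pi * t / 25) + np.sin(2 * np.pi * t / 250)
        assert estimate_period(x, 2.5) == pytest.approx(25.0, abs=2.5)

    def test_matches_brute_force_autocorrelation(self, rng):
        t = np.arange(0, 150, 1.0)
        x = np.sin(2 * np.pi * t / 14) + 0.05 * rng.normal(size=t.size)
        assert estimate_period(x, 1.0) == pytest.approx(
            brute_autocorr_period(x, 1.0), abs=1.0
        )


class TestBaseline:
    def test_constant_trace_gives_zero_corrected(self):
        b, c = subtract_baseline(np.full(30, 5.0), 5)
        np.testing.assert_allclose(b, 5.0)
        np.testing.assert_allclose(c, 0.0)

    def test_sinusoid_one_period_window_closed_form(self):
        # C + A sin with a one-period window: baseline C - A everywhere,
        # corrected peaks at 2A.  Sampling grid hits the sinusoid minimum
        # (phase -pi/2) and the trace ends on a period boundary so the
        # edge-truncated windows still contain a minimum sample.
        n, period, A, C = 241, 24, 3.0, 10.0
        x = C + A * np.sin(2 * np.pi * np.arange(n) / period - np.pi / 2)
        b, c = subtract_baseline(x, period)
        np.testing.assert_allclose(b, C - A, atol=1e-12)
        assert c.max() == pytest.approx(2 * A)
        assert c.min() >= 0

    def test_linear_drift_bounded_by_slope_times_window(self):
        n, period, A, slope = 400, 20, 2.0, 0.01
        t = np.arange(n, dtype=float)
        x = slope * t + A * np.sin(2 * np.pi * t / period - np.pi / 2)
        _, c = subtract_baseline(x, period)
        peaks = c[period : n - period].reshape(-1, period).max(axis=1)
        assert np.ptp(peaks) <= slope * period + 1e-9

    def test_corrected_nonnegative_on_random_traces(self, rng):
        for _ in range(20):
            x = rng.normal(size=rng.integers(10, 200))
            _, c = subtract_baseline(x, 7)
            assert (c >= 0).all()

    def test_periodicity_preserved_for_exact_period_window(self):
        n, period = 240, 24
        x = np.sin(2 * np.pi * np.arange(n) / period)
        _, c = subtract_baseline(x, period)
        mid = c[period : n - period]
        np.testing.assert_allclose(mid, np.roll(mid, period)[: len(mid)][: len(mid)], atol=1e-9)

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ValueError):
            subtract_baseline(np.ones(5), 10)


class TestDetectPeaks:
    def test_monotone_ramp_has_no_peaks(self):
        t = np.arange(20.0)
        train = detect_peaks(t.copy(), t)
        assert train.n_peaks == 0

    def test_triangle_wave_three_cycles(self):
        t = np.arange(30.0)
        x = np.abs((((t + 5.0) / 10.0) % 1.0) - 0.5)  # 3 triangular cycles
        train = detect_peaks(x, t, prominence=0.2, refine_times=False)
        assert train.n_peaks == 3
        assert len(train.trough_times) == 2
        # peaks and troughs interleave, peaks above flanking troughs
        merged = np.sort(np.concatenate([train.peak_times, train.trough_times]))
        assert np.all(np.diff(merged) > 0)
        assert (train.peak_values[:-1] >= train.trough_values).all()
        assert (train.peak_values[1:] >= train.trough_values).all()

    def test_generator_trace_peaks_match_schedule(self, single_droplet_layout):
        _, rois = single_droplet_layout
        ts = simulate_traces(
            rois, {"d0": LifecycleSchedule()}, noise=NoiseConfig.none(), seed=0
        )
        res = analyze_trace(ts.trace("d0"))
        gt = np.asarray(ts.ground_truth.wave_times["d0"])
        det = res.peaks.peak_times
        assert len(det) == len(gt)
        assert np.abs(det - gt).max() <= 1.0 / ts.sample_rate_hz

    def test_curation_edits_applied_after_detection(self):
        t = np.arange(50.0)
        x = np.zeros(50)
        x[10], x[30] = 5.0, 5.0
        train = detect_peaks(x, t, prominence=1.0)
        assert list(train.peak_indices) == [10, 30]
        curated = detect_peaks(
            x, t, prominence=1.0,
            curation=[
                {"action": "remove", "time_s": 30.0, "tolerance_s": 1.0},
                {"action": "add", "time_s": 40.0},
            ],
        )
        assert list(curated.peak_indices) == [10, 40]


class TestInstantaneousFrequency:
    def test_regular_train_gives_constant_frequency(self):
        # 25 s spacing: 0.04 s^-1, the study's main-stage value
        times, freqs = instantaneous_frequency(np.arange(0, 250, 25.0))
        np.testing.assert_allclose(freqs, 0.04)
        np.testing.assert_allclose(times, np.arange(25.0, 250, 25.0))

    def test_single_peak_empty(self):
        times, freqs = instantaneous_frequency(np.array([5.0]))
        assert times.size == freqs.size == 0

    def test_reciprocal_arithmetic(self):
        _, freqs = instantaneous_frequency(np.array([0.0, 10.0, 30.0]))
        np.testing.assert_allclose(freqs, [0.1, 0.05])


class TestSegmentation:
    def test_peakless_trace_is_induction_then_exhausted(self):
        seg = segment_periods(np.empty(0), t_start=0.0, t_end=100.0)
        assert seg.labels == ["induction", "exhausted"]
        assert seg.interval("induction").duration_s == 100.0

    def test_generator_schedule_boundaries_recovered(self, single_droplet_layout):
        _, rois = single_droplet_layout
        sched = LifecycleSchedule()
        ts = simulate_traces(rois, {"d0": sched}, noise=NoiseConfig.none(), seed=2)
        res = analyze_trace(ts.trace("d0"))
        bounds = ts.ground_truth.stage_bounds["d0"]
        main = res.segmentation.interval("main")
        period = 1.0 / sched.main.frequency_per_s
        assert main.start_s == pytest.approx(bounds["main"][0], abs=period)
        assert main.end_s == pytest.approx(bounds["main"][1], abs=period)
        initial = res.segmentation.interval("initial")
        assert initial.start_s == pytest.approx(
            bounds["initial"][0], abs=1.0 / sched.initial.frequency_per_s
        )

    def test_intervals_contiguous_and_ordered(self, single_droplet_layout):
        _, rois = single_droplet_layout
        ts = simulate_traces(rois, {"d0": LifecycleSchedule()}, seed=5)
        seg = analyze_trace(ts.trace("d0")).segmentation
        for a, b in zip(seg.intervals, seg.intervals[1:]):
            assert a.end_s == pytest.approx(b.start_s)
        assert seg.labels[-1] == "exhausted"


class TestPeakArea:
    def test_zero_segment(self):
        t = np.arange(10.0)
        assert peak_area(np.zeros(10), t, 0, 9) == 0.0

    def test_triangle_closed_form(self):
        # base 10 s, height 1 -> area 5
        t = np.arange(11.0)
        x = np.interp(t, [0, 5, 10], [0, 1, 0])
        assert peak_area(x, t, 0, 10) == pytest.approx(5.0)

    def test_linear_in_intensity_scale(self, rng):
        t = np.arange(30.0)
        x = np.abs(rng.normal(size=30))
        a1 = peak_area(x, t, 2, 27)
        a3 = peak_area(3 * x, t, 2, 27)
        assert a3 == pytest.approx(3 * a1)


class TestSummarize:
    def test_empty_peak_train_gives_zero_wave_count(self):
        t = np.arange(0, 100, 1.0)
        trace = IntensityTrace(t, np.zeros_like(t))
        res = analyze_trace(trace)
        assert res.features.wave_count == 0
        assert res.features.median_frequency_per_s is None
        assert res.features.median_amplitude is None

    def test_low_median_convention(self):
        assert low_median([1.0, 2.0, 3.0, 4.0]) == 2.0
        assert low_median([1, 2, 3, 4, 100]) == 3.0
        assert math.isnan(low_median([]))

    def test_wave_count_matches_schedule(self, single_droplet_layout):
        _, rois = single_droplet_layout
        ts = simulate_traces(rois, {"d0": LifecycleSchedule()}, seed=3)
        res = analyze_trace(ts.trace("d0"))
        scheduled = len(ts.ground_truth.wave_times["d0"])
        assert abs(res.features.wave_count - scheduled) <= 2

    def test_median_amplitude_of_known_heights(self):
        t = np.arange(100.0)
        x = np.zeros(100)
        heights = [1.0, 2.0, 3.0, 4.0, 100.0]
        for i, h in enumerate(heights):
            x[10 + 15 * i] = h
        trace = IntensityTrace(t, x)
        trace.corrected = x
        peaks = detect_peaks(x, t, prominence=0.5, refine_times=False)
        seg = segment_periods(peaks, t_start=0.0, t_end=99.0)
        feats = summarize_features(trace, peaks, seg)
        assert feats.median_amplitude == 3.0


class TestInvariances:
    def test_constant_offset_absorbed_by_baseline(self, single_droplet_layout):
        _, rois = single_droplet_layout
        ts = simulate_traces(rois, {"d0": LifecycleSchedule()}, seed=4)
        tr1 = ts.trace("d0")
        tr2 = IntensityTrace(tr1.time_s.copy(), tr1.raw + 500.0, droplet_id="d0")
        r1, r2 = analyze_trace(tr1), analyze_trace(tr2)
        assert r1.features.wave_count == r2.features.wave_count
        assert r1.features.median_frequency_per_s == pytest.approx(
            r2.features.median_frequency_per_s
        )
        assert r1.features.median_amplitude == pytest.approx(
            r2.features.median_amplitude, rel=1e-6
        )
        assert r1.features.median_area == pytest.approx(
            r2.features.median_area, rel=1e-6
        )

    @given(seed=st.integers(min_value=0, max_value=5))
    @settings(deadline=None, max_examples=6)
    def test_parameter_recovery_with_and_without_noise(self, seed):
        from bzkymo.geometry import make_linear_layout

        _, rois = make_linear_layout(1)
        sched = LifecycleSchedule()
        gt_waves = None
        for noise, tol in ((NoiseConfig.none(), 0.02), (NoiseConfig(), 0.05)):
            ts = simulate_traces(rois, {"d0": sched}, noise=noise, seed=seed)
            if gt_waves is None:
                gt_waves = np.asarray(ts.ground_truth.wave_times["d0"])
            gt_median = low_median(1.0 / np.diff(gt_waves))
            res = analyze_trace(ts.trace("d0"))
            assert res.features.median_frequency_per_s == pytest.approx(
                gt_median, rel=tol
            )
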