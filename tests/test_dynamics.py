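"""Region traces: binning, onset, slope, normalization, dilation counting."""

import dataclasses

import numpy as np
import pytest

from oisdyn import cbv, dynamics, pipeline, synthetic as syn


def _trace(values, rate=10.0, onset=5.0, baseline_bins=None):
    values = np.asarray(values, dtype=float)
    times = np.arange(values.size) * 0.3 + 0.1
    nb = baseline_bins if baseline_bins is not None else int(onset / 0.3)
    base = values[:nb]
    return dynamics.RegionTrace(
        values=values, bin_times_s=times, bin_duration_s=0.3,
        baseline_mean=float(base.mean()), baseline_sd=float(base.std(ddof=0)),
        stim_onset_s=onset,
    )


class TestBinning:
    def test_simple_arithmetic(self):
        assert np.allclose(dynamics.bin_by_three([1, 2, 3, 4, 5, 6]), [2.0, 5.0])

    def test_partial_final_bin(self):
        out = dynamics.bin_by_three(np.arange(200.0))
        assert out.size == 67
        assert out[-1] == pytest.approx((198 + 199) / 2)  # 2-frame partial bin

    def test_constant_series(self):
        assert np.allclose(dynamics.bin_by_three(np.full(30, 7.0)), 7.0)


class TestRegionTraceConstruction:
    def test_constant_field_gives_flat_trace(self):
        resp = cbv.ResponseMovie(
            pct_change=np.full((60, 8, 8), 2.0), frame_rate_hz=10.0,
            pixel_size_mm=0.05, stim_onset_s=3.0, stim_duration_s=2.0,
            baseline_frames=30,
        )
        tr = dynamics.intensity_trace(resp, np.ones((8, 8), bool))
        assert np.allclose(tr.values, 2.0)
        assert tr.n_bins == 20

    def test_single_pixel_region(self, rng):
        pct = rng.normal(size=(60, 8, 8))
        resp = cbv.ResponseMovie(pct, 10.0, 0.05, 3.0, 2.0, 30)
        region = np.zeros((8, 8), bool)
        region[4, 5] = True
        tr = dynamics.intensity_trace(resp, region)
        assert np.allclose(tr.values, dynamics.bin_by_three(pct[:, 4, 5]))

    def test_masked_mean_matches_bruteforce(self, rng):
        pct = rng.normal(size=(60, 10, 10))
        region = rng.random((10, 10)) > 0.6
        resp = cbv.ResponseMovie(pct, 10.0, 0.05, 3.0, 2.0, 30)
        tr = dynamics.intensity_trace(resp, region)
        manual = np.array([pct[t][region].mean() for t in range(60)])
        assert np.allclose(tr.values, dynamics.bin_by_three(manual))

    def test_empty_region_rejected(self, rng):
        resp = cbv.ResponseMovie(rng.normal(size=(60, 8, 8)), 10.0, 0.05, 3.0, 2.0, 30)
        with pytest.raises(ValueError):
            dynamics.intensity_trace(resp, np.zeros((8, 8), bool))


class TestOnset:
    def test_flat_trace_has_no_onset(self):
        assert dynamics.onset_time(_trace(np.zeros(60))) is None

    def test_zero_noise_baseline_uses_epsilon_floor(self):
        values = np.zeros(60)
        values[20:] = 1.0  # bins at t >= 6.1 s
        tr = _trace(values)
        onset = dynamics.onset_time(tr)
        assert onset == pytest.approx(tr.bin_times_s[20] - 5.0)

    def test_matches_bruteforce_scan(self, rng):
        for _ in range(20):
            values = np.concatenate([rng.normal(0, 0.5, 17), rng.normal(2, 0.5, 43)])
            tr = _trace(values)
            onset = dynamics.onset_time(tr)
            thr = tr.baseline_mean + 2 * max(tr.baseline_sd, 1e-6)
            expected = None
            for i in range(60):
                if tr.bin_times_s[i] >= 5.0 and tr.values[i] > thr:
                    expected = tr.bin_times_s[i] - 5.0
                    break
            assert onset == expected


class TestSlopeAndNormalization:
    def test_linear_ramp_slope(self):
        # 0 -> 6% over the 3 s following onset, then flat
        values = np.zeros(60)
        ramp_bins = np.arange(17, 27)
        values[ramp_bins] = np.linspace(0.6, 6.0, 10)
        values[27:] = 6.0
        tr = _trace(values)
        onset = dynamics.onset_time(tr)
        slope = dynamics.rising_slope(tr, onset)
        assert slope == pytest.approx(2.0, rel=0.15)

    def test_peak_at_onset_rejected(self):
        values = np.zeros(60)
        values[17] = 5.0  # single post-onset spike: peak bin == onset bin
        with pytest.raises(ValueError):
            dynamics.rising_slope(_trace(values), dynamics.onset_time(_trace(values)))

    def test_doubling_peak_doubles_slope(self):
        for scale in (1.0, 2.0):
            values = np.zeros(60)
            values[17:27] = np.linspace(0.6, 6.0, 10) * scale
            values[27:] = 6.0 * scale
            tr = _trace(values)
            s = dynamics.rising_slope(tr, dynamics.onset_time(tr))
            if scale == 1.0:
                s1 = s
        assert s == pytest.approx(2 * s1)

    def test_normalize_scales_max_to_exactly_100(self):
        values = np.zeros(60)
        values[30] = 4.0
        out = dynamics.normalize_trace_to_100(_trace(values))
        assert out.values.max() == 100.0
        assert out.values[30] == pytest.approx(4.0 * 25.0)

    def test_normalize_idempotent_and_preserves_ttp(self):
        values = np.zeros(60)
        values[30] = 100.0
        tr = _trace(values)
        out = dynamics.normalize_trace_to_100(tr)
        assert np.allclose(out.values, tr.values)
        assert dynamics.peak_metrics(out).time_to_peak_s == dynamics.peak_metrics(tr).time_to_peak_s

    def test_nonpositive_max_rejected(self):
        with pytest.raises(ValueError):
            dynamics.normalize_trace_to_100(_trace(np.full(60, -1.0)))


class TestPeakMetrics:
    def test_flat_trace(self):
        m = dynamics.peak_metrics(_trace(np.zeros(60)))
        assert m.max_change_pct == 0.0
        assert m.onset_time_s is None
        assert m.rising_slope_pct_per_s is None

    def test_internally_consistent_on_noiseless_render(self, noiseless_params):
        p = dataclasses.replace(noiseless_params, dilation_pct=6.48, n_trials=1)
        truth = syn.generate_vessel_tree(p)
        movie = pipeline.preprocess_trials(syn.render_trials(p, truth))
        region = truth.norm_dist_dilating <= 1.0
        static = truth.norm_dist_static <= 1.0
        tr = dynamics.dilation_trace(movie, region, exclude=static)
        m = dynamics.peak_metrics(tr)
        assert m.onset_time_s is not None and m.rising_slope_pct_per_s is not None
        assert m.onset_time_s <= m.time_to_peak_s
        onset_abs = m.onset_time_s + p.stim_onset_s
        oi = int(np.argmin(np.abs(tr.bin_times_s - onset_abs)))
        pi = int(np.argmin(np.abs(tr.bin_times_s - (m.time_to_peak_s + p.stim_onset_s))))
        expected = (tr.values[pi] - tr.values[oi]) / (tr.bin_times_s[pi] - tr.bin_times_s[oi])
        assert m.rising_slope_pct_per_s == pytest.approx(expected)


class TestDilationTrace:
    def test_null_dilation_stays_near_zero(self, noiseless_params):
        p = dataclasses.replace(noiseless_params, peak_amplitude_pct=0.0)
        truth = syn.generate_vessel_tree(p)
        movie = pipeline.preprocess_trials(syn.render_trials(p, truth))
        region = truth.norm_dist_dilating <= 1.0
        tr = dynamics.dilation_trace(movie, region,
                                     exclude=truth.norm_dist_static <= 1.0)
        assert np.abs(tr.values).max() < 0.5

    def test_monotone_in_injected_dilation(self, noiseless_params):
        peaks = []
        for d in (2.0, 5.0, 10.0, 20.0):
            p = dataclasses.replace(noiseless_params, dilation_pct=d,
                                    peak_amplitude_pct=0.0, n_trials=1)
            truth = syn.generate_vessel_tree(p)
            movie = pipeline.preprocess_trials(syn.render_trials(p, truth))
            tr = dynamics.dilation_trace(movie, truth.norm_dist_dilating <= 1.0,
                                         exclude=truth.norm_dist_static <= 1.0)
            peaks.append(dynamics.peak_metrics(tr).max_change_pct)
        assert all(b > a for a, b in zip(peaks, peaks[1:]))

    def test_empty_region_rejected(self, noiseless_params):
        truth = syn.generate_vessel_tree(noiseless_params)
        movie = pipeline.preprocess_trials(
            syn.render_trials(noiseless_params, truth)
        )
        with pytest.raises(ValueError):
            dynamics.dilation_trace(movie, np.zeros(truth.vessel_mask.shape, bool))
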