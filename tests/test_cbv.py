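"""CBV response pipeline: averaging, filtering, normalization, ROI, metrics."""

import numpy as np
import pytest

from oisdyn import cbv
from oisdyn.io import OISMovie


def _movie(frames, rate=10.0, nb=50, pixel=0.05):
    return OISMovie(
        frames=np.asarray(frames, dtype=float), frame_rate_hz=rate,
        pixel_size_mm=pixel, stim_onset_s=nb / rate, stim_duration_s=5.0,
        n_baseline_frames=nb,
    )


def _response(pct, rate=10.0, pixel=0.05, onset=5.0):
    return cbv.ResponseMovie(
        pct_change=np.asarray(pct, dtype=float), frame_rate_hz=rate,
        pixel_size_mm=pixel, stim_onset_s=onset, stim_duration_s=5.0,
        baseline_frames=int(onset * rate),
    )


class TestAverageTrials:
    def test_identical_trials_average_to_themselves(self):
        m = _movie(np.random.default_rng(0).uniform(50, 100, (60, 6, 6)), nb=10)
        avg = cbv.average_trials([m] * 8)
        assert np.allclose(avg.frames, m.frames)

    def test_two_constant_movies(self):
        a = _movie(np.full((60, 4, 4), 100.0), nb=10)
        b = _movie(np.full((60, 4, 4), 102.0), nb=10)
        assert np.allclose(cbv.average_trials([a, b]).frames, 101.0)

    def test_noise_reduction_sqrt_n(self, rng):
        """Averaging 8 trials of white noise shrinks the SD by ~sqrt(8)."""
        sigma = 2.0
        trials = [
            _movie(100.0 + rng.normal(0, sigma, (20, 100, 100)), nb=5)
            for _ in range(8)
        ]
        avg = cbv.average_trials(trials)
        measured = (avg.frames - 100.0).std()
        assert measured == pytest.approx(sigma / np.sqrt(8), rel=0.10)

    def test_shape_mismatch_raises(self):
        a = _movie(np.full((60, 4, 4), 1.0), nb=10)
        b = _movie(np.full((60, 4, 5), 1.0), nb=10)
        with pytest.raises(ValueError):
            cbv.average_trials([a, b])


class TestLowpass:
    def test_constant_movie_unchanged(self):
        m = _movie(np.full((200, 4, 4), 123.0))
        out = cbv.lowpass_filter(m, 1.0)
        assert np.allclose(out.frames, 123.0, atol=1e-9)

    def _sine_attenuation(self, freq, cutoff):
        t = np.arange(400) / 10.0
        sig = 100.0 + 10.0 * np.sin(2 * np.pi * freq * t)
        m = _movie(sig[:, None, None] * np.ones((1, 2, 2)))
        out = cbv.lowpass_filter(m, cutoff).frames[:, 0, 0]
        core = slice(100, 300)  # avoid filtfilt edge transients
        return (out[core] - 100.0).std() / (sig[core] - 100.0).std()

    def test_stopband_rejects_4hz(self):
        assert self._sine_attenuation(4.0, 1.0) <= 0.10

    def test_passband_preserves_slow_response(self):
        assert self._sine_attenuation(0.2, 1.0) == pytest.approx(1.0, abs=0.05)

    def test_invalid_cutoff(self):
        m = _movie(np.full((200, 2, 2), 1.0))
        with pytest.raises(ValueError):
            cbv.lowpass_filter(m, 5.0)  # at Nyquist


class TestNormalize:
    def test_constant_movie_gives_zero(self):
        m = _movie(np.full((100, 4, 4), 77.0))
        assert np.allclose(cbv.normalize_to_baseline(m).pct_change, 0.0)

    def test_reflectance_dip_reports_positive_cbv(self):
        frames = np.full((100, 2, 2), 100.0)
        frames[60] = 96.0
        resp = cbv.normalize_to_baseline(_movie(frames))
        assert resp.pct_change[60, 0, 0] == pytest.approx(4.0)

    def test_raw_sign_keeps_intensity_convention(self):
        frames = np.full((100, 2, 2), 100.0)
        frames[60] = 96.0
        resp = cbv.normalize_to_baseline(_movie(frames), sign="raw")
        assert resp.pct_change[60, 0, 0] == pytest.approx(-4.0)

    def test_zero_baseline_pixel_is_named(self):
        frames = np.full((100, 3, 3), 50.0)
        frames[:50, 1, 2] = 0.0
        with pytest.raises(ValueError, match=r"row=1, col=2"):
            cbv.normalize_to_baseline(_movie(frames))

    def test_average_then_normalize_commutes_for_shared_baseline(self, rng):
        """For noiseless trials with a common baseline, normalizing the
        average equals averaging the normalizations (linearity)."""
        base = rng.uniform(50, 100, (8, 8))
        trials = []
        for k in range(4):
            mod = 1.0 - 0.01 * (k + 1) * rng.uniform(0, 1, (30, 1, 1))
            mod[:10] = 1.0  # identical pre-stimulus baseline in every trial
            trials.append(_movie(base[None] * mod, nb=10))
        a = cbv.normalize_to_baseline(cbv.average_trials(trials)).pct_change
        b = np.mean(
            [cbv.normalize_to_baseline(t).pct_change for t in trials], axis=0
        )
        assert np.allclose(a, b, rtol=1e-9, atol=1e-9)


class TestCrop:
    def test_side_rounded_to_odd_pixel_count(self):
        resp = _response(np.zeros((10, 101, 101)))
        out = cbv.crop_to_window(resp, 50, 50, side_mm=3.0)  # 60 px -> 61
        assert out.pct_change.shape[1:] == (61, 61)

    def test_idempotent(self):
        resp = _response(np.arange(10 * 101 * 101, dtype=float).reshape(10, 101, 101))
        once = cbv.crop_to_window(resp, 50, 50, 3.0)
        twice = cbv.crop_to_window(once, 30, 30, 3.0)
        assert np.array_equal(once.pct_change, twice.pct_change)

    def test_corner_center_rejected(self):
        resp = _response(np.zeros((10, 101, 101)))
        with pytest.raises(ValueError):
            cbv.crop_to_window(resp, 0, 0, 3.0)


class TestSelectRoi:
    def test_finds_single_hot_block(self):
        pct = np.zeros((60, 30, 30))
        pct[50:, 12:19, 5:12] = 5.0
        roi = cbv.select_roi(_response(pct))
        assert (roi.top_row, roi.left_col) == (12, 5)

    def test_tie_broken_lexicographically(self):
        pct = np.zeros((60, 40, 40))
        pct[50:, 20:27, 30:37] = 5.0
        pct[50:, 3:10, 8:15] = 5.0
        roi = cbv.select_roi(_response(pct))
        assert (roi.top_row, roi.left_col) == (3, 8)

    def test_matches_exhaustive_search(self, rng):
        """50 random fields: the integral-image ROI equals brute force."""
        for _ in range(50):
            pct = rng.normal(size=(12, 20, 20))
            resp = _response(pct, onset=0.5)
            roi = cbv.select_roi(resp, size=7)
            tmax = pct[5:].max(axis=0)
            best, best_pos = -np.inf, None
            for r in range(14):
                for c in range(14):
                    score = tmax[r : r + 7, c : c + 7].mean()
                    if score > best + 1e-12:
                        best, best_pos = score, (r, c)
            assert (roi.top_row, roi.left_col) == best_pos


class TestRoiTrace:
    def test_constant_field(self):
        resp = _response(np.full((20, 10, 10), 2.0))
        trace = cbv.roi_trace(resp, cbv.RoiSelection(1, 1, 7))
        assert trace.shape == (20,)
        assert np.allclose(trace, 2.0)

    def test_single_hot_pixel_dilutes_by_roi_area(self):
        pct = np.zeros((5, 10, 10))
        pct[:, 4, 4] = 4.0
        trace = cbv.roi_trace(_response(pct), cbv.RoiSelection(1, 1, 7))
        assert np.allclose(trace, 4.0 / 49.0)


class TestMaxCbvAndTtp:
    def test_flat_trace_reports_zero_at_onset(self):
        m = cbv.max_cbv_and_ttp(np.zeros(200), 10.0, 5.0)
        assert m.max_change_pct == 0.0
        assert m.time_to_peak_s == 0.0

    def test_isolated_spike_is_three_frame_averaged(self):
        trace = np.ones(200)
        trace[:50] = 0.0
        trace[100] = 10.0
        m = cbv.max_cbv_and_ttp(trace, 10.0, 5.0)
        assert m.max_change_pct == pytest.approx((10 + 1 + 1) / 3)
        # frames 99 and 100 tie at (1+10+1)/3; ties go to the earliest
        assert m.time_to_peak_s == pytest.approx((99 - 50) / 10.0)

    def test_recovers_known_peak_time(self):
        """A smooth bump peaking 4.6 s after onset is located within one frame."""
        t = np.arange(200) / 10.0
        trace = 4.0 * np.exp(-((t - 9.6) ** 2) / 4.0)
        m = cbv.max_cbv_and_ttp(trace, 10.0, 5.0)
        assert abs(m.time_to_peak_s - 4.6) <= 0.1
        assert m.max_change_pct == pytest.approx(4.0, abs=0.1)


class TestActivationExtent:
    def test_zero_movie(self):
        resp = _response(np.zeros((10, 20, 20)))
        assert np.all(cbv.activation_extent(resp) == 0.0)

    def test_counting_arithmetic(self):
        pct = np.zeros((3, 20, 20))
        pct[:, 5:10, 5:10] = 2.0  # 25 pixels
        area = cbv.activation_extent(_response(pct, pixel=0.05), 1.0)
        assert np.allclose(area, 25 * 0.05**2)

    def test_threshold_is_strict(self):
        pct = np.full((3, 5, 5), 1.0)
        assert np.all(cbv.activation_extent(_response(pct), 1.0) == 0.0)

    def test_extent_monotone_in_threshold(self, rng):
        resp = _response(rng.normal(1.0, 1.0, size=(10, 30, 30)))
        areas = [cbv.activation_extent(resp, th).sum() for th in (0.5, 1.0, 1.5, 2.0)]
        assert all(a >= b for a, b in zip(areas, areas[1:]))
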