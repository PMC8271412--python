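import numpy as np
import pytest

import sleeppos as sp
from sleeppos.circular import circ_dist, wrap_angle
from sleeppos.io_core import AccelRecording
from sleeppos.orientation import calibrate, median_filter, raw_angle, resample_uniform


class TestResampleUniform:
    def test_linear_interpolation_between_two_samples(self):
        rec = AccelRecording(t=np.array([0.0, 1.0]),
                             acc=np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        out = resample_uniform(rec, rate=2.0)
        assert out.ax[1] == pytest.approx(0.5)

    def test_uniform_input_is_identity(self):
        t = np.arange(100) * 0.1
        acc = np.random.default_rng(0).normal(size=(100, 3))
        out = resample_uniform(AccelRecording(t=t, acc=acc))
        assert np.allclose(out.t, t, atol=1e-12)
        assert np.allclose(out.acc, acc, atol=1e-12)

    def test_matches_pointwise_interpolation_oracle(self):
        rng = np.random.default_rng(1)
        t = np.sort(rng.uniform(0, 30, size=400))
        t = t[np.concatenate(([True], np.diff(t) > 1e-4))]
        acc = rng.normal(size=(t.size, 3))
        out = resample_uniform(AccelRecording(t=t, acc=acc))
        # independent per-point linear interpolation
        for gi in range(0, out.n_samples, 7):
            g = out.t[gi] + t[0]
            j = np.searchsorted(t, g, side="right")
            j = min(max(j, 1), t.size - 1)
            w = (g - t[j - 1]) / (t[j] - t[j - 1])
            expected = (1 - w) * acc[j - 1] + w * acc[j]
            assert np.allclose(out.acc[gi], expected, atol=1e-9)

    def test_requires_two_samples(self):
        rec = AccelRecording(t=np.array([0.0]), acc=np.ones((1, 3)))
        with pytest.raises(ValueError):
            resample_uniform(rec)


class TestMedianFilter:
    def test_constant_series_unchanged(self):
        rec = AccelRecording(t=np.arange(1000) * 0.1, acc=np.full((1000, 3), 0.7))
        assert np.allclose(median_filter(rec).acc, 0.7)

    def test_single_spike_removed(self):
        acc = np.full((1000, 3), 0.5)
        acc[500] = 5.0
        rec = AccelRecording(t=np.arange(1000) * 0.1, acc=acc)
        assert np.allclose(median_filter(rec).acc, 0.5)

    def test_matches_naive_sliding_median(self):
        rng = np.random.default_rng(2)
        n = 1200  # 2 min at 10 Hz
        rec = AccelRecording(t=np.arange(n) * 0.1, acc=rng.normal(size=(n, 3)))
        out = median_filter(rec, window=60.0)
        half = 300
        for i in range(0, n, 37):
            lo, hi = max(0, i - half), min(n, i + half + 1)
            assert np.allclose(out.acc[i], np.median(rec.acc[lo:hi], axis=0), atol=1e-12)

    def test_non_positive_window_rejected(self):
        rec = AccelRecording(t=np.arange(10) * 0.1, acc=np.ones((10, 3)))
        with pytest.raises(ValueError):
            median_filter(rec, window=0.0)


class TestRawAngle:
    @pytest.mark.parametrize(
        "x, z, c, expected",
        [
            (0.0, 1.0, 1.0, 90.0),    # pure supine
            (1.0, 0.0, 0.0, 0.0),     # pure left; sign(0) := +1
            (0.0, -1.0, -1.0, -90.0),  # pure prone
            (np.sqrt(2) / 2, np.sqrt(2) / 2, 1.0, 45.0),
            (-1.0, 0.0, 0.0, 180.0),  # pure right maps to +180
        ],
    )
    def test_canonical_orientations(self, x, z, c, expected):
        assert raw_angle(x, z, c) == pytest.approx(expected, abs=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            raw_angle(0.0, 0.0, 1.0)

    def test_array_input_flags_degenerate_samples(self):
        out = raw_angle(np.array([0.0, 0.0]), np.array([1.0, 0.0]), np.array([1.0, 0.0]))
        assert out[0] == pytest.approx(90.0)
        assert np.isnan(out[1])


class TestCalibrate:
    def _series(self, sleep_vals):
        n = len(sleep_vals)
        t = np.arange(n) * 0.1
        return t, np.asarray(sleep_vals, float), np.full(n, 90.0)

    def test_constant_offset_recovered(self):
        t, s, st = self._series([80.0] * 6500)
        cal = calibrate(t, s, st)
        assert cal.theta_initial_sleep == pytest.approx(10.0, abs=1e-9)
        assert cal.theta_initial_stand == pytest.approx(0.0, abs=1e-9)

    def test_already_centred_gives_zero(self):
        t, s, st = self._series([90.0] * 6500)
        assert calibrate(t, s, st).theta_initial_sleep == pytest.approx(0.0, abs=1e-9)

    def test_noisy_supine_recovered_within_sampling_error(self):
        rng = np.random.default_rng(5)
        draw = wrap_angle(95.0 + rng.normal(0, 3.0, size=6500))
        t = np.arange(6500) * 0.1
        cal = calibrate(t, draw, np.full(6500, 90.0))
        se = 3.0 / np.sqrt(6500)
        assert cal.theta_initial_sleep == pytest.approx(-5.0, abs=3 * se + 0.01)

    def test_short_recording_falls_back_to_zero(self):
        t, s, st = self._series([70.0] * 100)
        cal = calibrate(t, s, st)
        assert cal.theta_initial_sleep == 0.0


class TestComputeAngles:
    def _uniform_rec(self, vec, n=100):
        return AccelRecording(t=np.arange(n) * 0.1, acc=np.tile(vec, (n, 1)))

    def test_supine_gravity_vector(self):
        series = sp.compute_angles(self._uniform_rec([0.0, 0.0, 1.0]), autocalibrate=False)
        assert np.allclose(series.sleep_angle, 90.0)
        assert np.allclose(series.stand_angle, 90.0)

    def test_standing_vector_near_180(self):
        series = sp.compute_angles(self._uniform_rec([0.02, -0.98, 0.1]), autocalibrate=False)
        assert np.all(np.abs(series.stand_angle) > 170)

    def test_scale_invariance(self):
        rng = np.random.default_rng(7)
        rec = AccelRecording(t=np.arange(200) * 0.1, acc=rng.normal(0, 1, size=(200, 3)))
        a = sp.compute_angles(rec, autocalibrate=False)
        b = sp.compute_angles(rec.scaled(2.5), autocalibrate=False)
        assert np.allclose(a.sleep_angle, b.sleep_angle, equal_nan=True)
        assert np.allclose(a.stand_angle, b.stand_angle, equal_nan=True)

    def test_offsets_rewrap_into_range(self):
        rec = self._uniform_rec([-1.0, 0.0, 0.05])  # raw sleep near 180
        cal = sp.CalibrationParams(theta_initial_sleep=30.0)
        series = sp.compute_angles(rec, calibration=cal)
        assert np.all(series.sleep_angle > -180) and np.all(series.sleep_angle <= 180)
        assert np.allclose(series.sleep_angle, wrap_angle(raw_angle(-1.0, 0.05, 0.05) + 30.0))


def test_pipeline_recovers_planted_angles(default_night, processed_night):
    """Steady-state sleep angles survive the resample→filter→angle chain
    to within 2° RMS at the generator's default noise (samples within 35 s
    of a posture change are excluded: the 60-s median filter is designed to
    smooth straight through those transients)."""
    truth = default_night.truth
    series = processed_night
    n = min(series.n_samples, truth.t.size)
    steady = np.ones(n, dtype=bool)
    for iv in truth.intervals:
        for edge in (iv.t_start, iv.t_end):
            steady &= np.abs(truth.t[:n] - edge) > 35.0
    steady &= np.isfinite(truth.sleep_angle[:n]) & series.valid[:n]
    err = circ_dist(series.sleep_angle[:n][steady], truth.sleep_angle[:n][steady])
    assert np.sqrt(np.mean(err**2)) < 2.0
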