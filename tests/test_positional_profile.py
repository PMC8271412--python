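import numpy as np
import pytest

import sleeppos as sp
from sleeppos.circular import circ_dist, circ_mean
from sleeppos.oximetry import DesatEvent
from sleeppos.positional_profile import (
    AnalysisConfig,
    PositionalProfile,
    grid_angles,
    local_odi,
    pct_de,
    pct_position,
    ratio_de_position,
)
from tests.conftest import make_series

GRID = grid_angles()


# --- independent brute-force oracles (naive double loops) -------------------

def brute_counts(angles, half=7.5):
    angles = np.asarray(angles, float)
    return np.array([np.sum(circ_dist(angles, th) <= half) for th in GRID], float)


def brute_local_odi(event_angles, sample_angles, cfg, smooth):
    ev = brute_counts(event_angles, cfg.half_window)
    pos = brute_counts(sample_angles, cfg.half_window)
    hours = pos / cfg.samples_per_hour
    odi = ev / np.maximum(hours, cfg.min_position_minutes / 60.0)
    valid = pos > 0
    odi[~valid] = np.nan
    if not smooth:
        return odi, valid
    out = np.full(360, np.nan)
    for i in range(360):
        if not valid[i]:
            continue
        neigh = [(i + k) % 360 for k in range(-cfg.smooth_radius, cfg.smooth_radius + 1)]
        vals = [odi[j] for j in neigh if valid[j]]
        out[i] = np.mean(vals)
    return out, valid


def random_inputs(seed, n_samples=6000, n_events=40):
    rng = np.random.default_rng(seed)
    sample_angles = rng.uniform(-180.0, 180.0, size=n_samples)
    event_angles = rng.uniform(-180.0, 180.0, size=n_events)
    return sample_angles, event_angles


def events_at(angles):
    out = []
    for a in np.atleast_1d(angles):
        ev = DesatEvent(0.0, 1.0, 2.0, 97.0, 93.0)
        ev.assigned_angle = float(a)
        out.append(ev)
    return out


class TestPctPosition:
    def test_point_mass_window_edges(self):
        series = make_series(np.full(600, 90.0))
        prof = pct_position(series)
        assert prof[GRID == 90][0] == pytest.approx(100.0)
        assert prof[GRID == 97][0] == pytest.approx(100.0)
        assert prof[GRID == 98][0] == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force(self, seed):
        samples, _ = random_inputs(seed)
        prof = pct_position(make_series(samples))
        expected = 100.0 * brute_counts(samples) / samples.size
        assert np.allclose(prof, expected, atol=1e-9)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_window_sum_conservation(self, seed):
        """Each sample sits in exactly 15 one-degree windows, so the profile
        sums to 1500 over the de-duplicated grid."""
        samples, _ = random_inputs(seed, n_samples=5000)
        assert pct_position(make_series(samples)).sum() == pytest.approx(1500.0, abs=1e-9)

    def test_empty_laying_rejected(self):
        series = make_series(np.full(100, 90.0), stand=178.0)
        with pytest.raises(ValueError):
            pct_position(series)


class TestAssignEventAngles:
    def test_constant_angle(self):
        series = make_series(np.full(600, 90.0))
        ev = [DesatEvent(5.0, 20.0, 40.0, 97.0, 93.0)]
        assert sp.assign_event_angles(ev, series)[0].assigned_angle == pytest.approx(90.0)

    def test_wrap_case(self):
        series = make_series(np.array([179.0, -179.0] * 300))
        ev = [DesatEvent(0.0, 20.0, 60.0, 97.0, 93.0)]
        assert sp.assign_event_angles(ev, series)[0].assigned_angle == pytest.approx(180.0)

    def test_matches_per_event_circular_mean(self, default_night, processed_night):
        events = sp.detect_desaturations(default_night.spo2)
        assigned = sp.assign_event_angles(list(events), processed_night)
        for ev in assigned[::3]:
            sel = ((processed_night.t >= ev.t_baseline)
                   & (processed_night.t <= ev.t_end) & processed_night.valid)
            expected = circ_mean(processed_night.sleep_angle[sel])
            assert circ_dist(ev.assigned_angle, expected) < 1e-9

    def test_event_outside_series_dropped_with_warning(self):
        series = make_series(np.full(100, 90.0))
        ev = [DesatEvent(500.0, 520.0, 540.0, 97.0, 93.0)]
        with pytest.warns(UserWarning, match="dropped"):
            assert sp.assign_event_angles(ev, series) == []


class TestPctDe:
    def test_single_event(self):
        prof = pct_de(events_at(90.0))
        assert prof[GRID == 90][0] == 100.0
        assert prof[GRID == 0][0] == 0.0

    def test_three_of_four_in_window(self):
        prof = pct_de(events_at([88.0, 90.0, 92.0, 160.0]))
        assert prof[GRID == 90][0] == pytest.approx(75.0)

    @pytest.mark.parametrize("seed", [5, 6])
    def test_matches_brute_force_and_conserves(self, seed):
        _, ev_angles = random_inputs(seed)
        prof = pct_de(events_at(ev_angles))
        expected = 100.0 * brute_counts(ev_angles) / ev_angles.size
        assert np.allclose(prof, expected, atol=1e-9)
        assert prof.sum() == pytest.approx(1500.0, abs=1e-9)

    def test_zero_events_warns_all_zero(self):
        with pytest.warns(UserWarning):
            assert pct_de([]).sum() == 0.0


class TestLocalOdi:
    def test_one_hour_at_supine(self):
        series = make_series(np.full(36000, 90.0))
        odi, valid = local_odi(events_at([90.0] * 5), series, smooth=False)
        assert odi[GRID == 90][0] == pytest.approx(5.0)
        assert valid[GRID == 90][0]

    def test_denominator_clamped_at_ten_minutes(self):
        series = make_series(np.full(3000, 150.0))  # 5 min
        odi, _ = local_odi(events_at([150.0] * 3), series, smooth=False)
        assert odi[GRID == 150][0] == pytest.approx(18.0)

    def test_unvisited_angles_masked(self):
        series = make_series(np.full(36000, 90.0))
        odi, valid = local_odi(events_at([90.0]), series, smooth=False)
        assert not valid[GRID == 0][0]
        assert np.isnan(odi[GRID == 0][0])

    @pytest.mark.parametrize("smooth", [False, True])
    def test_matches_brute_force(self, smooth):
        samples, ev_angles = random_inputs(7, n_samples=6000, n_events=30)
        cfg = AnalysisConfig()
        odi, valid = local_odi(events_at(ev_angles), make_series(samples), cfg,
                               smooth=smooth)
        expected, evalid = brute_local_odi(ev_angles, samples, cfg, smooth)
        assert np.array_equal(valid, evalid)
        assert np.allclose(odi, expected, atol=1e-9, equal_nan=True)


class TestRatio:
    def test_plain_and_clamped_and_masked(self):
        de = np.array([50.0, 10.0, 5.0])
        pos = np.array([25.0, 0.5, 0.0])
        padded = np.zeros(360)
        ratio, valid = ratio_de_position(np.concatenate([de, padded[3:]]),
                                         np.concatenate([pos, padded[3:]]))
        assert ratio[0] == pytest.approx(2.0)
        assert ratio[1] == pytest.approx(10.0)  # denominator floored at 1 %
        assert np.isnan(ratio[2]) and not valid[2]


class TestHeatmap:
    def _profile(self, hotspot, sid):
        rng = np.random.default_rng(8)
        pos = np.maximum(0.0, rng.normal(1.0, 0.3, size=360))
        de = np.exp(-0.5 * ((GRID - hotspot) / 10.0) ** 2) * 50.0
        odi = de.copy()
        odi[pos < 0.5] = np.nan
        valid = ~np.isnan(odi)
        ratio, rvalid = ratio_de_position(de, pos)
        return PositionalProfile(theta=GRID, pct_position=pos, pct_de=de,
                                 local_odi=odi, ratio=ratio, valid_odi=valid,
                                 valid_ratio=rvalid, subject_id=sid)

    def test_matrix_shapes_and_hotspot(self, tmp_path):
        profiles = [self._profile(90, "a"), self._profile(-90, "b")]
        written = sp.profile_heatmap(profiles, tmp_path, render=True)
        assert set(written) == {"pct_de", "pct_position", "ratio", "local_odi"}
        for name, item in written.items():
            assert item["matrix"].shape == (2, 360)
            assert item["csv"].exists()
        assert GRID[np.nanargmax(written["pct_de"]["matrix"][0])] == pytest.approx(90, abs=1)
        assert (tmp_path / "heatmap_local_odi.png").exists()

    def test_csv_round_trip_restores_mask(self, tmp_path):
        prof = self._profile(90, "a")
        path = prof.to_csv(tmp_path / "p.csv")
        back = PositionalProfile.from_csv(path)
        assert np.array_equal(np.isnan(back.local_odi), np.isnan(prof.local_odi))
        assert np.allclose(back.pct_de, prof.pct_de, atol=1e-5)
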