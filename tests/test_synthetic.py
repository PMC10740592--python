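"""Statistical structure of the synthetic telemetry generators."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist
from scipy.special import expit

from kelptrack import coa
from kelptrack.synthetic import (
    DetectionParams, MovementParams, simulate_array, simulate_detections,
    simulate_range_test, simulate_track, simulate_transmissions,
)
from kelptrack.io import ReceiverStation

from conftest import ORIGIN

FLAT = {"dawn": 1.0, "day": 1.0, "dusk": 1.0, "night": 1.0}
NO_MONTH = {m: 1.0 for m in range(1, 13)}


class TestArray:
    def test_single_station_at_origin(self):
        st = simulate_array(n_receivers=1, layout="grid", origin=ORIGIN)
        assert st["x"].iloc[0] == 0.0 and st["y"].iloc[0] == 0.0
        assert st["lon"].iloc[0] == pytest.approx(ORIGIN[0])

    def test_grid_spacing_lower_bound(self):
        st = simulate_array(n_receivers=29, spacing=500, layout="jittered-grid",
                            seed=5)
        assert len(st) == 29
        # jitter is bounded by ±20% of spacing per axis
        assert pdist(st[["x", "y"]].to_numpy()).min() >= 500 * (1 - 0.4) - 1e-9

    def test_deterministic_under_seed(self):
        a = simulate_array(seed=7)
        b = simulate_array(seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_spacing(self):
        with pytest.raises(ValueError):
            simulate_array(spacing=0)


class TestTrack:
    def test_zero_step_sd_stays_at_center(self):
        p = MovementParams(center_x=10.0, center_y=-5.0, step_sd=0.0, seed=1)
        tr = simulate_track(p, "2021-03-01T00:00Z", "2021-03-01T02:00Z")
        assert np.allclose(tr["x"], 10.0) and np.allclose(tr["y"], -5.0)

    def test_emigration_truncates(self):
        p = MovementParams(seed=1,
                           emigration_time=pd.Timestamp("2021-03-01T01:00Z"))
        tr = simulate_track(p, "2021-03-01T00:00Z", "2021-03-01T03:00Z")
        assert tr["t"].max() <= pd.Timestamp("2021-03-01T01:00Z")

    def test_pure_random_walk_msd_matches_diffusion_law(self):
        # attraction 0, flat multipliers: E|r(t)|^2 = 2 * step_sd^2 * t
        step_sd, dt, n_steps, reps = 2.0, 60.0, 40, 500
        finals = np.empty(reps)
        t0 = pd.Timestamp("2021-03-01T19:00Z")
        t1 = t0 + pd.Timedelta(seconds=dt * n_steps)
        for r in range(reps):
            p = MovementParams(attraction=0.0, step_sd=step_sd, dt=dt,
                               diel_speed_multiplier=FLAT,
                               monthly_speed_multiplier=NO_MONTH, seed=r)
            tr = simulate_track(p, t0, t1)
            finals[r] = tr["x"].iloc[-1] ** 2 + tr["y"].iloc[-1] ** 2
        expected = 2 * step_sd ** 2 * dt * n_steps
        assert abs(finals.mean() - expected) / expected < 0.2

    def test_deterministic_under_seed(self):
        p = MovementParams(seed=3)
        a = simulate_track(p, "2021-03-01T00:00Z", "2021-03-01T06:00Z")
        b = simulate_track(p, "2021-03-01T00:00Z", "2021-03-01T06:00Z")
        pd.testing.assert_frame_equal(a, b)


class TestTransmissions:
    def _hour_track(self):
        t = pd.date_range("2021-03-01T00:00Z", periods=61, freq="min")
        return pd.DataFrame({"t": t, "x": np.linspace(0, 600, 61),
                             "y": np.zeros(61)})

    def test_mean_ping_count_matches_renewal_rate(self):
        # gaps U(30,120): rate 1/75 per s -> about 48 pings per hour
        track = self._hour_track()
        counts = [len(simulate_transmissions(track, 30, 120, seed=s))
                  for s in range(200)]
        expected = 3600 / 75.0
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 2 * se + 0.5

    def test_fixed_interval_gaps_exact(self):
        pings = simulate_transmissions(self._hour_track(), 60, 60, seed=0)
        gaps = pings["t"].diff().dropna().dt.total_seconds()
        assert np.allclose(gaps, 60.0)

    def test_positions_interpolated_on_track(self):
        pings = simulate_transmissions(self._hour_track(), 60, 60, seed=0)
        # x moves at 10 m/min along the track
        secs = (pings["t"] - pd.Timestamp("2021-03-01T00:00Z")).dt.total_seconds()
        assert np.allclose(pings["x"], secs / 6.0)

    def test_empty_track_no_pings(self):
        empty = pd.DataFrame(columns=["t", "x", "y"])
        assert simulate_transmissions(empty, 30, 120, seed=0).empty


class TestDetections:
    def _pings_at(self, xy, n):
        t = pd.date_range("2021-03-01T00:00Z", periods=n, freq="30s")
        return pd.DataFrame({"t": t, "x": np.full(n, xy[0]),
                             "y": np.full(n, xy[1])})

    def test_detection_rate_at_station_matches_logistic_intercept(self):
        stations = simulate_array(n_receivers=1, layout="grid", origin=ORIGIN)
        dp = DetectionParams(beta0=4.0, beta1=-0.02, receiver_slope_sd=0.0,
                             seed=0)
        dets = simulate_detections(self._pings_at((0, 0), 10_000), stations, dp)
        p = expit(4.0)
        se = np.sqrt(p * (1 - p) / 10_000)
        assert abs(len(dets) / 10_000 - p) < 3 * se

    def test_steep_slope_silences_distant_pings(self):
        stations = simulate_array(n_receivers=1, layout="grid", origin=ORIGIN)
        dp = DetectionParams(beta0=4.0, beta1=-10.0, receiver_slope_sd=0.0,
                             seed=0)
        dets = simulate_detections(self._pings_at((50, 0), 2_000), stations, dp)
        assert dets.empty

    def test_deterministic_under_seed(self):
        stations = simulate_array(n_receivers=4, seed=1)
        dp = DetectionParams(seed=9)
        pings = self._pings_at((100, 100), 500)
        a = simulate_detections(pings, stations, dp)
        b = simulate_detections(pings, stations, dp)
        pd.testing.assert_frame_equal(a, b)


class TestRangeTest:
    STATION = ReceiverStation("R01", lat=32.85, lon=-117.27, depth=18.0)

    def test_heading_mirror_symmetry(self):
        dp = DetectionParams(seed=0)
        east = simulate_range_test(self.STATION, 0.2, 90.0, dp, 1800, seed=4)
        west = simulate_range_test(self.STATION, 0.2, 270.0, dp, 1800, seed=4)
        # identical distance profiles, mirrored longitudes
        assert np.allclose(east["lat"], west["lat"], atol=1e-12)
        assert np.allclose(east["lon"] - self.STATION.lon,
                           -(west["lon"] - self.STATION.lon), atol=1e-12)
        assert (east["detected"] == west["detected"]).all()

    def test_short_drift_detected_fraction_near_intercept(self):
        dp = DetectionParams(beta0=2.0, beta1=-0.02, receiver_slope_sd=0.0)
        logs = [simulate_range_test(self.STATION, 0.01, 0.0, dp, 600, seed=s,
                                    min_interval=1.0, max_interval=2.0)
                for s in range(30)]
        frac = pd.concat(logs)["detected"].mean()
        assert frac == pytest.approx(expit(2.0), abs=0.05)

    def test_deterministic_under_seed(self):
        dp = DetectionParams(seed=0)
        a = simulate_range_test(self.STATION, 0.2, 45.0, dp, 1200, seed=2)
        b = simulate_range_test(self.STATION, 0.2, 45.0, dp, 1200, seed=2)
        pd.testing.assert_frame_equal(a, b)


class TestEndToEndRecovery:
    def test_coa_mean_near_activity_center(self):
        """A tightly home-ranged fish's COAs average near its centre."""
        stations = simulate_array(n_receivers=9, spacing=400, layout="grid",
                                  origin=ORIGIN, seed=0)
        p = MovementParams(center_x=80.0, center_y=-60.0, step_sd=0.8,
                           attraction=0.5, diel_speed_multiplier=FLAT,
                           monthly_speed_multiplier=NO_MONTH, seed=11)
        track = simulate_track(p, "2021-03-01T00:00Z", "2021-03-03T00:00Z")
        pings = simulate_transmissions(track, seed=3)
        dets = simulate_detections(pings, stations, DetectionParams(seed=5),
                                   origin=ORIGIN)
        coas = coa.compute_coas(dets, stations, interval=1800, origin=ORIGIN)
        assert abs(coas["x"].mean() - 80.0) < 400
        assert abs(coas["y"].mean() + 60.0) < 400
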