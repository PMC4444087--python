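"""Drift trajectories, set maps, beaching detection and ineffective effort."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from driftstate.downstream import (
    BeachingConfig,
    compare_set_maps,
    detect_beachings,
    extract_sea_trajectories,
    fishing_grounds,
    grid_density,
    ineffective_effort,
    predicted_fishing_sets,
    smooth_density,
    trajectory_summary,
)

T0 = pd.Timestamp("2010-01-01")


def _classified(states, lats=None, lons=None, hours=None, bid="b"):
    n = len(states)
    return pd.DataFrame(
        {
            "buoy_id": bid,
            "time": T0 + pd.to_timedelta(hours if hours is not None else range(n), unit="h"),
            "lat": lats if lats is not None else np.zeros(n),
            "lon": lons if lons is not None else np.linspace(10, 10 + 0.01 * n, n),
            "state": list(states),
        }
    )


class TestTrajectories:
    def test_single_interior_run(self):
        traj = extract_sea_trajectories(_classified("BBSSSBB"))
        assert len(traj) == 1
        assert traj.loc[0, "n_positions"] == 3
        assert traj.loc[0, "end_event"] == "retrieval"

    def test_all_sea_track(self):
        traj = extract_sea_trajectories(_classified("SSSS"))
        assert len(traj) == 1
        assert traj.loc[0, "end_event"] == "track_end"

    def test_stationary_run_duration_and_distance(self):
        df = _classified("SSS", lats=[1, 1, 1], lons=[2, 2, 2], hours=[0, 24, 48])
        traj = extract_sea_trajectories(df)
        assert traj.loc[0, "duration_days"] == pytest.approx(2.0)
        assert traj.loc[0, "distance_km"] == 0.0

    def test_position_conservation(self, fleet):
        traj = extract_sea_trajectories(fleet.buoys)
        n_b = (fleet.buoys["state"] == "B").sum()
        assert traj["n_positions"].sum() + n_b == len(fleet.buoys)


class TestSummary:
    def test_hand_arithmetic(self):
        traj = pd.DataFrame(
            {
                "duration_days": [1.0, 3.0],
                "end_time": [T0, T0],
                "start_time": [T0, T0],
            }
        )
        s = trajectory_summary(traj)
        assert s.loc[0, "mean"] == 2.0
        assert s.loc[0, "sd"] == pytest.approx(np.sqrt(2))
        assert s.loc[0, "se"] == pytest.approx(1.0)

    def test_single_trajectory_flagged(self):
        traj = pd.DataFrame({"duration_days": [5.0], "end_time": [T0], "start_time": [T0]})
        s = trajectory_summary(traj)
        assert np.isnan(s.loc[0, "sd"]) and np.isnan(s.loc[0, "se"])

    def test_month_groups_partition(self):
        traj = pd.DataFrame(
            {
                "duration_days": [1, 2, 3, 4.0],
                "end_time": pd.to_datetime(
                    ["2010-01-05", "2010-01-20", "2010-02-01", "2010-03-10"]
                ),
                "start_time": [T0] * 4,
            }
        )
        s = trajectory_summary(traj, group_by="month")
        assert s["n"].sum() == 4
        assert set(s["group"]) == {1, 2, 3}


class TestPredictedSets:
    def test_single_transition(self):
        sets = predicted_fishing_sets(_classified("BBSSSB"))
        assert len(sets) == 1
        # 5th position (index 4) ends the S run
        assert sets.loc[0, "time"] == T0 + pd.Timedelta(hours=4)

    def test_all_onboard_none(self):
        assert len(predicted_fishing_sets(_classified("BBBB"))) == 0

    def test_count_equals_sb_transitions(self, rng):
        for _ in range(30):
            states = "".join(rng.choice(["S", "B"], rng.integers(2, 40)))
            n_trans = sum(1 for a, b in zip(states, states[1:]) if a == "S" and b == "B")
            assert len(predicted_fishing_sets(_classified(states))) == n_trans


class TestGridDensity:
    def test_floor_convention(self):
        pts = pd.DataFrame({"lat": [10.5], "lon": [-5.5]})
        d = grid_density(pts)
        assert (d.loc[0, "cell_lat"], d.loc[0, "cell_lon"]) == (10, -6)

    def test_half_open_cells(self):
        pts = pd.DataFrame({"lat": [10.0], "lon": [4.0]})
        d = grid_density(pts)
        assert (d.loc[0, "cell_lat"], d.loc[0, "cell_lon"]) == (10, 4)

    def test_counts_conserved(self, rng):
        pts = pd.DataFrame({"lat": rng.uniform(-10, 10, 500), "lon": rng.uniform(30, 60, 500)})
        assert grid_density(pts)["count"].sum() == 500


class TestSmoothDensity:
    def test_integrates_to_one(self, rng):
        pts = pd.DataFrame({"lat": rng.normal(0, 2, 200), "lon": rng.normal(40, 2, 200)})
        gx, gy, dens = smooth_density(pts)
        integral = np.trapezoid(np.trapezoid(dens, gx, axis=1), gy)
        assert 0.99 <= integral <= 1.01

    def test_unimodal_at_cluster_mean(self, rng):
        pts = pd.DataFrame(
            {"lat": rng.normal(5, 0.1, 100), "lon": rng.normal(45, 0.1, 100)}
        )
        gx, gy, dens = smooth_density(pts)
        iy, ix = np.unravel_index(np.argmax(dens), dens.shape)
        assert abs(gy[iy] - 5) < 0.3
        assert abs(gx[ix] - 45) < 0.3

    def test_doubling_bandwidth_lowers_peak(self, rng):
        pts = pd.DataFrame({"lat": rng.normal(0, 1, 150), "lon": rng.normal(0, 1, 150)})
        _, _, d1 = smooth_density(pts, bandwidth=(1.0, 1.0))
        _, _, d2 = smooth_density(pts, bandwidth=(2.0, 2.0))
        assert d2.max() < d1.max()

    def test_matches_mass_kde2d_oracle(self, rng, tmp_path):
        """Independent oracle: R's MASS::kde2d on the same points/grid."""
        x = rng.uniform(0, 10, 40).round(6)
        y = rng.uniform(0, 5, 40).round(6)
        pts = pd.DataFrame({"lon": x, "lat": y})
        h = (1.5, 1.2)
        lims = (-2.0, 12.0, -2.0, 7.0)
        gx, gy, dens = smooth_density(pts, bandwidth=h, gridsize=25, extent=lims)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(MASS))
            x <- c({','.join(map(str, x))})
            y <- c({','.join(map(str, y))})
            k <- kde2d(x, y, h=c(1.5, 1.2), n=25, lims=c(-2, 12, -2, 7))
            write.csv(k$z, "{tmp_path}/z.csv", row.names=FALSE)
            """
        )
        (tmp_path / "kde.R").write_text(script)
        subprocess.run(["Rscript", str(tmp_path / "kde.R")], check=True, capture_output=True)
        z_r = pd.read_csv(tmp_path / "z.csv").to_numpy()  # indexed [x, y]
        np.testing.assert_allclose(dens, z_r.T, rtol=1e-8, atol=1e-12)


class TestSetMapComparison:
    def test_identical_maps_rho_one(self, rng):
        pts = pd.DataFrame({"lat": rng.uniform(0, 5, 50), "lon": rng.uniform(0, 5, 50)})
        rho, n = compare_set_maps(pts, pts.copy())
        assert rho == 1.0

    def test_disjoint_single_cells(self):
        obs = pd.DataFrame({"lat": [0.5], "lon": [0.5]})
        pre = pd.DataFrame({"lat": [3.5, 3.6, 3.7], "lon": [3.5, 3.5, 3.5]})
        rho, n = compare_set_maps(obs, pre)
        assert n == 2
        assert np.isnan(rho)  # flagged unreliable below 3 cells

    def test_anticorrelated_maps(self):
        # counts 3,2,1 vs 1,2,3 over the same three cells: reversed ranks
        obs = pd.DataFrame({"lat": [0.5] * 3 + [1.5] * 2 + [2.5], "lon": [0.5] * 6})
        pre = pd.DataFrame({"lat": [0.5] + [1.5] * 2 + [2.5] * 3, "lon": [0.5] * 6})
        rho, n = compare_set_maps(obs, pre)
        assert rho == pytest.approx(-1.0)

    def test_rank_invariance_under_scaling(self, rng):
        pts = pd.DataFrame({"lat": rng.uniform(0, 5, 60), "lon": rng.uniform(0, 5, 60)})
        other = pd.DataFrame({"lat": rng.uniform(0, 5, 60), "lon": rng.uniform(0, 5, 60)})
        rho1, _ = compare_set_maps(pts, other)
        tripled = pd.concat([other] * 3, ignore_index=True)
        rho3, _ = compare_set_maps(pts, tripled)
        assert rho1 == pytest.approx(rho3)


class TestBeachingDetector:
    COAST = np.array([[-5.0, 0.0], [5.0, 0.0]])
    PORTS = np.array([[0.0, 0.0]])

    def _raw(self, coords, hours=None, bid="b"):
        n = len(coords)
        return pd.DataFrame(
            {
                "buoy_id": bid,
                "time": T0 + pd.to_timedelta(hours if hours else range(0, 6 * n, 6), unit="h"),
                "lat": [c[0] for c in coords],
                "lon": [c[1] for c in coords],
            }
        )

    def test_three_repeats_near_coast_far_from_port(self):
        # 3 identical fixes ~3 km from the coastline, ~330 km from the port
        raw = self._raw([(3.0, 0.03)] * 3)
        ev = detect_beachings(raw, self.PORTS, self.COAST)
        assert len(ev) == 1
        assert bool(ev.loc[0, "within_coast"])

    def test_two_repeats_no_event(self):
        raw = self._raw([(3.0, 0.03)] * 2 + [(3.1, 0.1)])
        ev = detect_beachings(raw, self.PORTS, self.COAST)
        assert len(ev) == 0

    def test_port_anchorage_excluded(self):
        # 4 identical fixes 5 km from the port
        from driftstate.geo import destination_point

        lat, lon = destination_point(0.0, 0.0, 90.0, 5.0)
        raw = self._raw([(lat, lon)] * 4)
        ev = detect_beachings(raw, self.PORTS, self.COAST)
        assert len(ev) == 0

    def test_offshore_repeats_flagged_not_within_coast(self):
        raw = self._raw([(3.0, 3.0)] * 4)  # ~330 km from the coast
        ev = detect_beachings(raw, self.PORTS, self.COAST)
        assert len(ev) == 1
        assert not bool(ev.loc[0, "within_coast"])

    def test_min_repeats_floor(self):
        with pytest.raises(ValueError):
            BeachingConfig(min_repeats=2)


class TestGroundsAndEffort:
    def test_single_set_single_cell(self):
        sets = pd.DataFrame({"lat": [2.5], "lon": [40.5], "time": [T0]})
        assert fishing_grounds(sets) == {(2, 40)}

    def test_three_cells(self):
        sets = pd.DataFrame(
            {"lat": [0.5, 1.5, 2.5], "lon": [40.5, 40.5, 40.5], "time": [T0] * 3}
        )
        assert len(fishing_grounds(sets)) == 3

    def test_nested_fleets_monotone(self):
        french = pd.DataFrame({"lat": [0.5, 1.5], "lon": [40.5, 41.5], "time": [T0] * 2})
        all_fleets = pd.concat(
            [french, pd.DataFrame({"lat": [5.5], "lon": [45.5], "time": [T0]})]
        )
        assert fishing_grounds(all_fleets) >= fishing_grounds(french)

    def test_fraction_all_inside(self):
        df = _classified("SSS", lats=[0.5, 0.5, 0.5], lons=[40.2, 40.4, 40.6])
        effort, _, _ = ineffective_effort(df, {(0, 40)})
        assert effort.loc[0, "fraction_outside"] == 0.0

    def test_fraction_all_outside(self):
        df = _classified("SSS", lats=[5.5, 5.5, 5.5], lons=[50.2, 50.4, 50.6])
        effort, _, shares = ineffective_effort(df, {(0, 40)})
        assert effort.loc[0, "fraction_outside"] == 1.0
        assert shares[0.5] == 1.0

    def test_interval_attribution_to_start_cell(self):
        # two 12-h intervals: first starts inside, second starts outside
        df = _classified(
            "SSS", lats=[0.5, 0.5, 0.5], lons=[40.5, 41.5, 42.5], hours=[0, 12, 24]
        )
        effort, _, _ = ineffective_effort(df, {(0, 40)})
        assert effort.loc[0, "fraction_outside"] == pytest.approx(0.5)

    def test_single_fix_trajectory_excluded(self):
        df = _classified("SB", lats=[0.5, 0.5], lons=[40.5, 40.6])
        effort, _, shares = ineffective_effort(df, {(0, 40)})
        assert effort.loc[0, "total_days"] == 0.0
        assert np.isnan(effort.loc[0, "fraction_outside"])
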