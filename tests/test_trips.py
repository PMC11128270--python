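import numpy as np
import pandas as pd
import pytest

from divekit import trips as T
from divekit.geo import offset_lonlat
from divekit.simulate import SimulationConfig, simulate_cohort

COLONY = (146.6758, -38.9403)


def track_from_offsets(offsets_m, start="2021-09-20T00:00:00Z", interval_s=300):
    """Build a track from (east_m, north_m) offsets relative to the colony."""
    t0 = pd.Timestamp(start)
    rows = []
    for i, (east, north) in enumerate(offsets_m):
        lon, lat = offset_lonlat(COLONY[0], COLONY[1], east, north)
        rows.append({"timestamp": t0 + pd.Timedelta(seconds=i * interval_s),
                     "lon": float(lon), "lat": float(lat)})
    return pd.DataFrame(rows)


class TestSplitTrips:
    def test_never_leaves_buffer(self):
        track = track_from_offsets([(0, 0), (100, 100), (-200, 50), (0, 0)])
        assert T.split_trips(track, COLONY) == []

    def test_single_excursion(self):
        track = track_from_offsets([(0, 0), (2000, 0), (4000, 0), (2000, 0),
                                    (0, 0)])
        trips = T.split_trips(track, COLONY)
        assert len(trips) == 1
        trip = trips[0]
        assert trip.complete
        assert len(trip.fixes) == 5  # includes both boundary inside fixes
        # crossing interpolated between (t=0, 0 m) and (t=300, 2000 m)
        dep_s = (trip.departure_time - track["timestamp"].iloc[0]).total_seconds()
        assert dep_s == pytest.approx(300 * 500 / 2000, rel=1e-6)

    def test_boundary_fix_counts_inside(self):
        track = track_from_offsets([(0, 0), (3000, 0), (0, 0)])
        # replace last fix with one at exactly 500.0 m due north
        lat_500 = COLONY[1] + np.degrees(500.0 / 6_371_000.0)
        track.loc[2, ["lon", "lat"]] = [COLONY[0], lat_500]
        trips = T.split_trips(track, COLONY)
        assert len(trips) == 1
        assert trips[0].complete  # the 500.0 m fix closed the trip

    def test_incomplete_when_record_ends_outside(self):
        track = track_from_offsets([(0, 0), (2000, 0), (4000, 0)])
        trips = T.split_trips(track, COLONY)
        assert len(trips) == 1
        assert not trips[0].complete

    def test_collinear_fix_insertion_invariant(self):
        base = track_from_offsets([(0, 0), (2000, 0), (4000, 0), (2000, 0),
                                   (0, 0)])
        # insert a redundant midpoint between fixes 1 and 2
        extra = base.iloc[[1]].copy()
        extra["timestamp"] = base["timestamp"].iloc[1] + pd.Timedelta(seconds=150)
        lon_mid = (base["lon"].iloc[1] + base["lon"].iloc[2]) / 2
        extra["lon"] = lon_mid
        dense = (pd.concat([base, extra]).sort_values("timestamp")
                 .reset_index(drop=True))
        assert len(T.split_trips(dense, COLONY)) == len(T.split_trips(base, COLONY))

    def test_no_fix_lost(self):
        track = track_from_offsets([(0, 0), (2000, 0), (0, 0), (0, 100),
                                    (3000, 0), (5000, 0), (0, 0)])
        trips = T.split_trips(track, COLONY)
        outside = {1, 4, 5}
        covered = set()
        for trip in trips:
            for ts in trip.fixes["timestamp"]:
                covered.add(int((ts - track["timestamp"].iloc[0]).total_seconds()
                                // 300))
        assert outside <= covered

    def test_recovery_on_synthetic_cohort(self):
        cfg = SimulationConfig(seed=4, n_males=1, n_females=1, n_days=3,
                               overnight_roost_prob=0.0)
        _, deployments, truth = simulate_cohort(cfg)
        for dep in deployments:
            trips = T.split_trips(dep.track, cfg.colony_lonlat)
            tt = truth.trips[truth.trips["individual_id"] == dep.individual_id]
            assert len(trips) == len(tt)
            for trip, (_, row) in zip(trips, tt.iterrows()):
                dep_err = abs((trip.departure_time
                               - row["departure_time"]).total_seconds())
                ret_err = abs((trip.return_time
                               - row["return_time"]).total_seconds())
                assert dep_err <= cfg.gps_interval_s
                assert ret_err <= cfg.gps_interval_s


class TestTripStats:
    def test_square_trip_total(self):
        km = 1000.0
        track = track_from_offsets([(0, 0), (5000, 0), (5000 + km, 0),
                                    (5000 + km, km), (5000, km), (5000, 0),
                                    (0, 0)])
        trip = T.split_trips(track, COLONY)[0]
        # interior square of 1 km legs plus out-and-back 5 km transits
        assert trip.total_distance_km == pytest.approx(4 * 1.0 + 2 * 5.0,
                                                       rel=0.01)

    def test_out_and_back(self):
        track = track_from_offsets([(0, 0), (10_000, 0), (0, 0)])
        trip = T.split_trips(track, COLONY)[0]
        assert trip.max_distance_km == pytest.approx(10.0, rel=0.01)
        assert trip.total_distance_km == pytest.approx(20.0, rel=0.01)

    def test_cohort_duration_mean_matches_config(self):
        cfg = SimulationConfig(seed=21, n_males=3, n_females=3, n_days=6,
                               overnight_roost_prob=0.0,
                               trip_duration_sd_h=1.0)
        _, deployments, truth = simulate_cohort(cfg)
        durations = []
        for dep in deployments:
            for trip in T.split_trips(dep.track, cfg.colony_lonlat):
                if trip.complete:
                    durations.append(trip.duration_h)
        durations = np.asarray(durations)
        assert len(durations) >= 30
        se = durations.std(ddof=1) / np.sqrt(len(durations))
        assert abs(durations.mean() - cfg.trip_duration_mean_h) < 3 * se + 0.1


class TestOvernightRoost:
    def test_daytime_trip_not_roost(self, small_config, small_cohort):
        bathy, deployments, truth = small_cohort
        dep = deployments[0]
        trips = T.split_trips(dep.track, small_config.colony_lonlat)
        for trip in trips:
            tt = truth.trips[(truth.trips["individual_id"] == dep.individual_id)]
            # match by overlapping span
            match = tt[(tt["departure_time"] <= trip.return_time)
                       & (tt["return_time"] >= trip.departure_time)]
            if len(match) == 1 and not match["overnight_roost"].iloc[0]:
                assert not T.detect_overnight_roost(
                    trip, small_config.colony_lonlat, small_config.tz_offset_h)

    def test_roost_trip_detected(self):
        cfg = SimulationConfig(seed=8, n_males=2, n_females=2, n_days=4,
                               overnight_roost_prob=1.0)
        _, deployments, truth = simulate_cohort(cfg)
        flags = []
        for dep in deployments:
            for trip in T.split_trips(dep.track, cfg.colony_lonlat):
                if trip.complete:
                    flags.append(T.detect_overnight_roost(
                        trip, cfg.colony_lonlat, cfg.tz_offset_h))
        assert len(flags) > 0
        assert np.mean(flags) == 1.0

    def test_moving_overnight_not_roost(self):
        # crosses midnight but keeps moving > 200 m per 2 h window
        offs = [(0, 0)] + [(3000 + 400 * i, 0) for i in range(130)] + [(0, 0)]
        track = track_from_offsets(offs, start="2021-09-20T08:00:00Z",
                                   interval_s=600)
        trip = T.split_trips(track, COLONY)[0]
        assert (trip.return_time - trip.departure_time) > pd.Timedelta(hours=12)
        assert not T.detect_overnight_roost(trip, COLONY, 11.0)


class TestHistograms:
    def test_single_departure_bin(self):
        table = pd.DataFrame({
            "trip_id": ["t0"], "individual_id": ["a"], "sex": ["M"],
            "departure_time": [pd.Timestamp("2021-09-19T20:10:00Z")],  # 07:10 +11
            "return_time": [pd.Timestamp("2021-09-20T02:00:00Z")],
            "duration_h": [5.8], "total_distance_km": [10.0],
            "max_distance_km": [5.0], "complete": [True],
            "overnight_roost": [False]})
        hist = T.departure_return_histograms(table, tz_offset_h=11.0)
        row = hist[(hist["sex"] == "M") & (hist["hour"] == 7)]
        assert row["departures"].iloc[0] == 1
        assert hist["departures"].sum() == 1

    def test_counts_conserved(self, small_config, small_cohort):
        _, deployments, _ = small_cohort
        tables = []
        for dep in deployments:
            trips = T.split_trips(dep.track, small_config.colony_lonlat)
            tables.append(T.trips_table(trips, dep.individual_id, dep.sex))
        table = pd.concat(tables, ignore_index=True)
        hist = T.departure_return_histograms(table, small_config.tz_offset_h)
        n_complete = int(table["complete"].sum())
        assert hist["departures"].sum() == n_complete
        assert hist["returns"].sum() == n_complete
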