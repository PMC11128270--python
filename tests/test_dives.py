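import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from divekit.dives import (detect_dives, extract_dives, interpolate_dive_edges,
                           post_dive_intervals, summarize_dive,
                           zero_offset_correct)
from divekit.errors import IntegrityError, ValidationError

from conftest import make_pressure_series


def brute_force_runs(depths, threshold):
    """Independent reference: scan sample by sample for runs above threshold."""
    runs = []
    start = None
    for i, d in enumerate(depths):
        if d > threshold and start is None:
            start = i
        elif d <= threshold and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(depths) - 1))
    return runs


class TestZeroOffsetCorrect:
    def test_constant_offset_removed(self):
        series = make_pressure_series(np.full(500, 0.5))
        out = zero_offset_correct(series)
        assert np.allclose(out["depth_m"], 0.0)

    def test_offset_free_unchanged(self):
        depths = np.zeros(1000)
        depths[100:110] = [5, 10, 15, 20, 20, 20, 15, 10, 5, 2]
        series = make_pressure_series(depths)
        out = zero_offset_correct(series)
        assert np.allclose(out["depth_m"], depths, atol=1e-9)

    def test_idempotent(self):
        # surface sits at a constant sensor offset; dives carry noise
        rng = np.random.default_rng(3)
        depths = np.full(2000, 0.4)
        depths[500:520] += 15.0 + rng.normal(0, 0.2, 20)
        depths[1200:1230] += 8.0 + rng.normal(0, 0.2, 30)
        series = make_pressure_series(depths)
        once = zero_offset_correct(series)
        twice = zero_offset_correct(once)
        assert np.allclose(once["depth_m"], twice["depth_m"], atol=1e-9)

    def test_drifting_offset_recovered(self):
        # 24 h record, offset drifting 0 -> 1 m, square dives to 20 m
        n = 21600  # 4-s samples over 24 h
        drift = np.linspace(0.0, 1.0, n)
        depths = np.zeros(n)
        true_starts = np.arange(200, n - 200, 150)  # a dive every 10 min
        for s in true_starts:
            depths[s:s + 15] = 20.0
        series = make_pressure_series(depths + drift)
        out = zero_offset_correct(series)
        dives = detect_dives(out, 1.0)
        assert len(dives) == len(true_starts)
        for dive in dives:
            assert dive.max_depth_m == pytest.approx(20.0, abs=0.1)

    def test_empty_series_rejected(self):
        with pytest.raises(ValidationError):
            zero_offset_correct(make_pressure_series([]))


class TestDetectDives:
    def test_spec_single_dive(self):
        series = make_pressure_series([0, 2, 4, 4, 2, 0])
        dives = detect_dives(series, 1.0)
        assert len(dives) == 1
        assert dives[0].raw_first_s == 4.0
        assert dives[0].raw_last_s == 16.0

    def test_all_zero_no_dives(self):
        assert detect_dives(make_pressure_series(np.zeros(50)), 1.0) == []

    def test_single_sample_dive_kept(self):
        series = make_pressure_series([0, 5, 0])
        dives = detect_dives(series, 1.0)
        assert len(dives) == 1
        assert dives[0].edge_fallback

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(0, 30, allow_nan=False), min_size=2, max_size=60),
           st.floats(0.5, 5.0))
    def test_matches_brute_force(self, depths, threshold):
        series = make_pressure_series(depths)
        dives = detect_dives(series, threshold)
        expected = brute_force_runs(depths, threshold)
        got = [(int(d.raw_first_s // 4), int(d.raw_last_s // 4)) for d in dives]
        assert got == expected


class TestEdgeInterpolation:
    def test_analytic_zero_crossing(self):
        # samples 2,4,4,2 m at t=4..16 with surface neighbours at t=0 and 20:
        # both edge lines cross zero depth exactly at those surface instants
        series = make_pressure_series([0, 2, 4, 4, 2, 0])
        dive = detect_dives(series, 1.0)[0]
        assert dive.start_s == pytest.approx(0.0, abs=1e-12)
        assert dive.end_s == pytest.approx(20.0, abs=1e-12)
        assert dive.duration_s == pytest.approx(20.0, abs=1e-12)

    def test_flat_edge_clamps_to_surface_sample(self):
        series = make_pressure_series([0, 4, 4, 4, 0])
        dive = detect_dives(series, 1.0)[0]
        assert dive.start_s == 0.0  # previous surface sample time
        assert dive.end_s == 16.0   # next surface sample time

    def test_duration_at_least_raw_span(self):
        rng = np.random.default_rng(9)
        depths = np.zeros(400)
        depths[50:60] = rng.uniform(2, 20, 10)
        depths[200:230] = rng.uniform(2, 20, 30)
        for dive in detect_dives(make_pressure_series(depths), 1.0):
            assert dive.duration_s >= dive.raw_last_s - dive.raw_first_s

    def test_steep_crossing_not_clamped(self):
        # line through (4 s, 3 m), (8 s, 6 m) crosses zero at t = 0;
        # ascent line through (8 s, 6 m), (12 s, 3 m) crosses zero at t = 16
        series = make_pressure_series([0, 3, 6, 3, 0])
        dive = detect_dives(series, 1.0)[0]
        (start, end) = interpolate_dive_edges(dive)
        assert start == pytest.approx(0.0)
        assert end == pytest.approx(16.0)


class TestSummaries:
    def test_vertical_distance_hand_sum(self):
        # edge legs 2 + 2, interior |4-2| + 0 + |2-4| -> total 8
        series = make_pressure_series([0, 2, 4, 4, 2, 0])
        dive = detect_dives(series, 1.0)[0]
        max_depth, duration, vdist = summarize_dive(dive)
        assert max_depth == 4.0
        assert vdist == pytest.approx(8.0)

    def test_triangle_identity(self):
        series = make_pressure_series([0, 2, 4, 2, 0])
        dive = detect_dives(series, 1.0)[0]
        assert dive.vertical_distance_m == pytest.approx(2 * dive.max_depth_m)

    def test_max_depth(self):
        series = make_pressure_series([0, 2, 4, 4, 2, 0])
        assert detect_dives(series, 1.0)[0].max_depth_m == 4.0


class TestPostDiveIntervals:
    def test_interval_between_two_dives(self):
        depths = np.zeros(60)
        depths[5:10] = 10.0
        depths[20:25] = 10.0
        dives = detect_dives(make_pressure_series(depths), 1.0)
        intervals = post_dive_intervals(dives)
        assert len(intervals) == 1
        # surface gap from interpolated end of dive 1 to start of dive 2
        assert intervals[0] == pytest.approx(dives[1].start_s - dives[0].end_s)
        assert intervals[0] > 0

    def test_single_dive_empty(self):
        depths = np.zeros(20)
        depths[5:10] = 10.0
        dives = detect_dives(make_pressure_series(depths), 1.0)
        assert post_dive_intervals(dives) == []

    def test_overlap_rejected(self):
        series = make_pressure_series([0, 5, 5, 0, 0, 5, 5, 0])
        dives = detect_dives(series, 1.0)
        dives[0].end_s = dives[1].start_s + 10.0  # corrupt
        with pytest.raises(IntegrityError):
            post_dive_intervals(dives)

    def test_durations_plus_intervals_cover_record(self):
        rng = np.random.default_rng(4)
        depths = np.zeros(2000)
        pos = 10
        while pos < 1950:
            width = rng.integers(3, 20)
            depths[pos:pos + width] = rng.uniform(5, 25)
            pos += width + rng.integers(3, 30)
        dives = detect_dives(make_pressure_series(depths), 1.0)
        intervals = post_dive_intervals(dives)
        total = sum(d.duration_s for d in dives) + sum(intervals)
        elapsed = dives[-1].end_s - dives[0].start_s
        assert total == pytest.approx(elapsed, abs=4.0 * len(dives))


class TestExtractDives:
    def test_table_schema_and_last_interval_nan(self):
        depths = np.zeros(60)
        depths[5:10] = 10.0
        depths[30:40] = 12.0
        table = extract_dives(make_pressure_series(depths), zoc=False)
        assert list(table.columns) == ["dive_id", "start", "end", "duration_s",
                                       "max_depth_m", "vertical_distance_m",
                                       "post_dive_s", "edge_fallback"]
        assert len(table) == 2
        assert np.isnan(table["post_dive_s"].iloc[-1])
        assert table["post_dive_s"].iloc[0] > 0

    def test_recovery_against_truth(self, small_config, small_cohort,
                                    small_classified):
        _, deployments, truth = small_cohort
        labelled, _, _ = small_classified
        for dep in deployments:
            mine = labelled[labelled["individual_id"] == dep.individual_id]
            td = truth.dives[truth.dives["individual_id"] == dep.individual_id]
            assert len(mine) == len(td)
            merged = pd.merge_asof(
                mine.sort_values("start"),
                td.sort_values("start")[["start", "duration_s", "max_depth_m"]]
                .rename(columns={"start": "ts", "duration_s": "true_dur",
                                 "max_depth_m": "true_depth"}),
                left_on="start", right_on="ts", direction="nearest",
                tolerance=pd.Timedelta(seconds=6))
            assert merged["true_dur"].notna().all()
            # duration recovered within ~2 sampling intervals
            err = (merged["duration_s"] - merged["true_dur"]).abs()
            assert err.median() < 2 * small_config.pressure_interval_s
            depth_err = (merged["max_depth_m"] - merged["true_depth"]).abs()
            assert depth_err.median() < 1.0
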