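import numpy as np
import pandas as pd
import pytest

from divekit import classify
from divekit import trips as trips_mod
from divekit.dives import extract_dives
from divekit.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=11, n_males=1, n_females=1, n_days=2)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """(bathymetry, deployments, truth) for a tiny two-bird cohort."""
    return simulate_cohort(small_config)


def classify_cohort(cfg, bathy, deployments):
    """Run extraction -> trips -> classification for every deployment.

    Returns (labelled dive table with individual_id/sex/year columns,
    list of per-deployment trip lists).
    """
    labelled_tables = []
    trip_lists = []
    for dep in deployments:
        dive_table = extract_dives(dep.pressure)
        trips = trips_mod.split_trips(dep.track, cfg.colony_lonlat)
        trip_ids = classify.assign_trip_ids(dive_table, trips)
        labelled, _ = classify.classify_deployment(
            dive_table, dep.track, bathy, trip_ids=trip_ids,
            gps_interval_s=cfg.gps_interval_s)
        labelled.insert(0, "individual_id", dep.individual_id)
        labelled.insert(1, "sex", dep.sex)
        labelled["year"] = dep.year
        labelled_tables.append(labelled)
        trip_lists.append(trips)
    table = (pd.concat(labelled_tables, ignore_index=True)
             if labelled_tables else pd.DataFrame())
    return table, trip_lists


def match_to_truth(labelled, truth_dives, tolerance_s=6.0):
    """merge_asof detected dives onto truth dives by start time."""
    left = labelled.sort_values("start").reset_index(drop=True)
    right = (truth_dives.sort_values("start")[["start", "dive_class", "duration_s",
                                               "max_depth_m"]]
             .rename(columns={"start": "true_start", "dive_class": "true_class",
                              "duration_s": "true_duration_s",
                              "max_depth_m": "true_max_depth_m"}))
    return pd.merge_asof(left, right, left_on="start", right_on="true_start",
                         direction="nearest",
                         tolerance=pd.Timedelta(seconds=tolerance_s))


@pytest.fixture(scope="session")
def small_classified(small_config, small_cohort):
    bathy, deployments, truth = small_cohort
    labelled, trip_lists = classify_cohort(small_config, bathy, deployments)
    return labelled, trip_lists, truth


def make_pressure_series(depths, interval_s=4.0, start="2021-09-20T00:00:00Z"):
    t0 = pd.Timestamp(start)
    times = t0 + pd.to_timedelta(np.arange(len(depths)) * interval_s, unit="s")
    return pd.DataFrame({"timestamp": times,
                         "depth_m": np.asarray(depths, dtype=float)})
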