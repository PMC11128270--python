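"""End-to-end orchestration: simulate or ingest, then run every stage.

A run is driven by a YAML config (see :data:`EXAMPLE_CONFIG`). Outputs are
CSV/GeoJSON/ASCII-grid files plus a JSON run report with per-stage counts,
timings and a file manifest. Reruns with the same config and seed produce
byte-identical CSV outputs.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import pandas as pd
import yaml

from . import adl, classify, diet, effort, io, spatial, trips as trips_mod
from .errors import ConfigurationError
from .simulate import SimulationConfig, simulate_cohort, simulate_diet_samples

_SCHEMA = {
    "simulate": bool,
    "seed": int,
    "out_dir": str,
    "buffer_m": (int, float),
    "min_depth_m": (int, float),
    "zoc_window_s": (int, float),
    "zoc_quantile": (int, float),
    "tz_offset_h": (int, float),
    "kde_h": (int, float),
    "grid_cells": int,
    "mask_to_95": bool,
    "input_dir": str,
    "simulation": dict,
}

DEFAULTS = {
    "simulate": True,
    "seed": 0,
    "out_dir": "divekit_out",
    "buffer_m": 500.0,
    "min_depth_m": 1.0,
    "zoc_window_s": 7200.0,
    "zoc_quantile": 0.05,
    "tz_offset_h": 11.0,
    "kde_h": 0.01,
    "grid_cells": 200,
    "mask_to_95": False,
    "simulation": {},
}

EXAMPLE_CONFIG = """\
simulate: true
seed: 1
out_dir: divekit_out
buffer_m: 500
min_depth_m: 1.0
tz_offset_h: 11
kde_h: 0.01
grid_cells: 200
simulation:
  n_males: 2
  n_females: 2
  n_days: 2
"""


def load_config(source) -> dict:
    """Load and validate a run config from a YAML path or a dict."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source or {})
    cfg = dict(DEFAULTS)
    for key, value in raw.items():
        if key not in _SCHEMA:
            raise ConfigurationError(f"unknown config field '{key}'")
        if not isinstance(value, _SCHEMA[key]) or isinstance(value, bool) and _SCHEMA[key] is not bool:
            raise ConfigurationError(
                f"config field '{key}' has invalid type {type(value).__name__}")
        cfg[key] = value
    if cfg["buffer_m"] <= 0:
        raise ConfigurationError("config field 'buffer_m' must be > 0")
    if cfg["min_depth_m"] <= 0:
        raise ConfigurationError("config field 'min_depth_m' must be > 0")
    if not cfg["simulate"] and "input_dir" not in cfg:
        raise ConfigurationError("config field 'input_dir' is required when simulate is false")
    return cfg


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime(io.TIMESTAMP_FORMAT)
    out.to_csv(path, index=False, float_format="%.8f")


def run_pipeline(config_source, log=print) -> dict:
    """Run every stage and return the run report (also written to report.json)."""
    cfg = load_config(config_source)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"parameters": {k: v for k, v in cfg.items()},
                    "seed": cfg["seed"], "counts": {}, "wall_time_s": {},
                    "outputs": []}
    manifest = report["outputs"]

    def stage(name):
        t_start = time.perf_counter()

        def done():
            report["wall_time_s"][name] = round(time.perf_counter() - t_start, 3)
            log(f"[divekit] stage {name} done in {report['wall_time_s'][name]:.2f}s")
        return done

    # ----- input stage: simulate or ingest
    done = stage("input")
    truth = None
    if cfg["simulate"]:
        sim_cfg = SimulationConfig(seed=cfg["seed"], **cfg["simulation"])
        bathy, deployments, truth = simulate_cohort(sim_cfg)
        diet_samples = simulate_diet_samples(sim_cfg)
        io.write_bathymetry(bathy, out_dir / "bathymetry.asc")
        manifest.append("bathymetry.asc")
        if len(truth.dives):
            _write_csv(truth.dives.drop(columns=["postdive_s"]),
                       out_dir / "truth_dives.csv")
            manifest.append("truth_dives.csv")
        if len(truth.trips):
            _write_csv(truth.trips, out_dir / "truth_trips.csv")
            manifest.append("truth_trips.csv")
        colony = sim_cfg.colony_lonlat
        gps_interval_s = sim_cfg.gps_interval_s
    else:
        in_dir = Path(cfg["input_dir"])
        if not in_dir.exists():
            raise ConfigurationError(f"input_dir does not exist: {in_dir}")
        bathy = io.read_bathymetry(in_dir / "bathymetry.asc")
        individuals = io.read_individuals_csv(in_dir / "individuals.csv")
        track_all = io.read_track_csv(in_dir / "tracks.csv")
        pressure_all = io.read_pressure_csv(in_dir / "pressure.csv")
        deployments = []
        for _, ind in individuals.iterrows():
            iid = ind["individual_id"]
            deployments.append(io.Deployment(
                individual_id=iid, sex=ind["sex"], mass_kg=float(ind["mass_kg"]),
                tarsus_mm=float(ind["tarsus_mm"]), year=int(ind["year"]),
                track=track_all[track_all["individual_id"] == iid].reset_index(drop=True),
                pressure=pressure_all[pressure_all["individual_id"] == iid].reset_index(drop=True)))
        diet_path = in_dir / "diet.csv"
        diet_samples = io.read_diet_csv(diet_path) if diet_path.exists() else pd.DataFrame()
        sim_cfg = None
        colony_cfg = cfg["simulation"].get("colony_lonlat")
        colony = tuple(colony_cfg) if colony_cfg else SimulationConfig().colony_lonlat
        gps_interval_s = None

    ind_table = pd.DataFrame([{
        "individual_id": d.individual_id, "sex": d.sex, "mass_kg": d.mass_kg,
        "tarsus_mm": d.tarsus_mm, "year": d.year} for d in deployments])
    if len(ind_table):
        io.write_individuals_csv(ind_table, out_dir / "individuals.csv")
        manifest.append("individuals.csv")
    if deployments:
        _write_csv(pd.concat([d.track for d in deployments], ignore_index=True),
                   out_dir / "tracks.csv")
        _write_csv(pd.concat([d.pressure for d in deployments], ignore_index=True),
                   out_dir / "pressure.csv")
        manifest += ["tracks.csv", "pressure.csv"]
    if len(diet_samples):
        io.write_diet_csv(diet_samples, out_dir / "diet.csv")
        manifest.append("diet.csv")
    report["counts"]["individuals"] = len(deployments)
    report["counts"]["gps_fixes"] = int(sum(len(d.track) for d in deployments))
    report["counts"]["pressure_samples"] = int(sum(len(d.pressure) for d in deployments))
    done()

    from .dives import extract_dives

    # ----- per-deployment stages
    done = stage("dives_trips_classify")
    dive_tables, trip_tables, effort_tables = [], [], []
    summaries = []
    for dep in deployments:
        dive_table = extract_dives(dep.pressure, min_depth_m=cfg["min_depth_m"],
                                   zoc_window_s=cfg["zoc_window_s"],
                                   zoc_quantile=cfg["zoc_quantile"])
        trip_list = trips_mod.split_trips(dep.track, colony, buffer_m=cfg["buffer_m"])
        for trip in trip_list:
            trips_mod.detect_overnight_roost(trip, colony, cfg["tz_offset_h"],
                                             buffer_m=cfg["buffer_m"])
        trip_table = trips_mod.trips_table(trip_list, dep.individual_id, dep.sex)
        trip_ids = classify.assign_trip_ids(dive_table, trip_list)
        trip_ids = trip_ids.map(lambda t: f"{dep.individual_id}_t{t}"
                                if not pd.isna(t) else t)
        labelled, summary = classify.classify_deployment(
            dive_table, dep.track, bathy, trip_ids=trip_ids,
            gps_interval_s=gps_interval_s)
        labelled.insert(0, "individual_id", dep.individual_id)
        labelled.insert(1, "sex", dep.sex)
        labelled["year"] = dep.year
        dive_tables.append(labelled)
        trip_tables.append(trip_table)
        summaries.append(summary)
        if len(dep.pressure):
            effort_tables.append(effort.hourly_dive_rate(
                labelled, dep.pressure["timestamp"].iloc[0],
                dep.pressure["timestamp"].iloc[-1], cfg["tz_offset_h"],
                individual_id=dep.individual_id, sex=dep.sex))
    dives_all = pd.concat(dive_tables, ignore_index=True) if dive_tables else pd.DataFrame()
    trips_all = pd.concat(trip_tables, ignore_index=True) if trip_tables else pd.DataFrame()
    effort_all = pd.concat(effort_tables, ignore_index=True) if effort_tables else pd.DataFrame()
    if len(dives_all):
        _write_csv(dives_all, out_dir / "dives.csv")
        manifest.append("dives.csv")
    if len(trips_all):
        _write_csv(trips_all, out_dir / "trips.csv")
        manifest.append("trips.csv")
    if len(effort_all):
        _write_csv(effort_all, out_dir / "effort.csv")
        manifest.append("effort.csv")
    report["counts"]["dives"] = len(dives_all)
    report["counts"]["trips"] = len(trips_all)
    report["counts"]["classified_dives"] = int(sum(s.n_classified for s in summaries))
    report["counts"]["unclassifiable_dives"] = int(sum(s.n_unclassifiable for s in summaries))
    done()

    # ----- aerobic dive limit
    done = stage("adl")
    adl_rows = []
    for dep in deployments:
        if not len(dives_all):
            break
        mine = dives_all[dives_all["individual_id"] == dep.individual_id]
        est = adl.estimate_adl(mine["duration_s"], mine["post_dive_s"],
                               individual_id=dep.individual_id)
        adl_rows.append({"individual_id": dep.individual_id, "sex": dep.sex,
                         "mass_kg": dep.mass_kg, "detected": est.detected,
                         "adl_s": est.adl_s, "slope_below": est.slope_below,
                         "slope_above": est.slope_above, "reason": est.reason})
    adl_table = pd.DataFrame(adl_rows)
    if len(adl_table):
        _write_csv(adl_table, out_dir / "adl.csv")
        manifest.append("adl.csv")
    report["counts"]["adl_detections"] = int(adl_table["detected"].sum()) if len(adl_table) else 0
    detected = adl_table[adl_table["detected"]] if len(adl_table) else pd.DataFrame()
    if len(detected) >= 3 and detected["mass_kg"].nunique() > 1:
        slope, intercept, r2, p = adl.adl_mass_regression(
            detected["adl_s"], detected["mass_kg"])
        report["adl_mass_regression"] = {"slope_s_per_kg": slope,
                                         "intercept_s": intercept,
                                         "r2": r2, "p": p}
    done()

    # ----- spatial overlap
    done = stage("overlap")
    overlap_rows = []
    if len(dives_all):
        usable = dives_all[dives_all["dive_class"] != "unclassifiable"]
        results = spatial.sex_overlap_by_year(usable, h=cfg["kde_h"],
                                              n_cells=cfg["grid_cells"])
        for res in results:
            overlap_rows.append({
                "year": res.year,
                "ba_index": res.ba_index_hr95 if cfg["mask_to_95"] else res.ba_index,
                "ba_index_full": res.ba_index,
                "ba_index_hr95": res.ba_index_hr95,
                "n_male_dives": res.n_male, "n_female_dives": res.n_female})
            for sex, ud in (("M", res.ud_male), ("F", res.ud_female)):
                _, poly = spatial.contour_95(ud)
                if poly is not None:
                    name = f"hr95_{res.year}_{sex}.geojson"
                    spatial.polygon_to_geojson(
                        poly, out_dir / name,
                        {"year": res.year, "sex": sex, "level": 0.95})
                    manifest.append(name)
    overlap_table = pd.DataFrame(overlap_rows)
    if len(overlap_table):
        _write_csv(overlap_table, out_dir / "overlap.csv")
        manifest.append("overlap.csv")
    report["counts"]["overlap_years"] = len(overlap_table)
    done()

    # ----- diet
    done = stage("diet")
    if len(diet_samples):
        foo = diet.foo_table(diet_samples, group_by=("sex", "year"))
        abundance = diet.numerical_abundance(diet_samples, group_by=("sex", "year"))
        summary = foo.merge(abundance, on=["sex", "year", "species", "n_samples"])
        _write_csv(summary, out_dir / "diet_summary.csv")
        manifest.append("diet_summary.csv")
        lengths = diet.prey_length_summary(diet_samples, group_by=("sex",))
        _write_csv(lengths, out_dir / "prey_lengths.csv")
        manifest.append("prey_lengths.csv")
        report["counts"]["diet_samples"] = int(diet_samples["sample_id"].nunique())
    else:
        report["counts"]["diet_samples"] = 0
    done()

    if truth is not None:
        report["truth_counts"] = {
            "dives": len(truth.dives), "trips": len(truth.trips),
            "individuals": len(truth.individuals)}
    report_path = out_dir / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    manifest.append("report.json")
    return report
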