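"""Locate dives on the GPS track and classify them benthic vs pelagic.

A dive is benthic when any of three criteria fires, evaluated in order so
the provenance of each label is recorded:

1. ``consecutive_10pct`` — its maximum depth is within 10% of either the
   previous or the subsequent dive in the same trip (the denominator is the
   larger of the two depths; see ``ratio_denominator``);
2. ``shallow_bathy``    — the seafloor at the dive location is < 10 m;
3. ``depth_vs_bathy``   — |dive depth − seafloor depth| < 5 m.

Otherwise the dive is pelagic. Dives over missing bathymetry are flagged
unclassifiable and excluded from proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import OutOfRangeError, ValidationError
from .io import BathymetryGrid

NEIGHBOUR_TOLERANCE = 0.10
SHALLOW_BATHY_M = 10.0
DEPTH_VS_BATHY_M = 5.0

CRITERIA = ("consecutive_10pct", "shallow_bathy", "depth_vs_bathy", "none")


def interpolate_dive_location(track: pd.DataFrame, time,
                              max_gap_intervals: float = 3.0,
                              gps_interval_s: float | None = None):
    """Linearly interpolate the track position at ``time``.

    Returns (lon, lat, low_confidence); the flag is set when the bracketing
    fixes are more than ``max_gap_intervals`` nominal GPS intervals apart.
    Raises :class:`OutOfRangeError` outside the track span.
    """
    ts = track["timestamp"]
    t = pd.Timestamp(time)
    if t < ts.iloc[0] or t > ts.iloc[-1]:
        raise OutOfRangeError(f"time {t} outside track span")
    tsec = (ts - ts.iloc[0]).dt.total_seconds().to_numpy()
    x = (t - ts.iloc[0]).total_seconds()
    lon = float(np.interp(x, tsec, track["lon"].to_numpy(dtype=float)))
    lat = float(np.interp(x, tsec, track["lat"].to_numpy(dtype=float)))
    j = int(np.searchsorted(tsec, x, side="right"))
    j = min(max(j, 1), len(tsec) - 1)
    gap = tsec[j] - tsec[j - 1]
    nominal = gps_interval_s if gps_interval_s is not None else float(np.median(np.diff(tsec)))
    low_conf = bool(gap > max_gap_intervals * nominal)
    return lon, lat, low_conf


def classify_dive(max_depth_m: float,
                  prev_max_depth_m: float | None,
                  next_max_depth_m: float | None,
                  seafloor_depth_m: float,
                  ratio_denominator: str = "max") -> tuple[str, str]:
    """Classify one dive; returns (dive_class, criterion_fired).

    ``ratio_denominator`` selects the base of the 10% neighbour comparison:
    ``"max"`` (default, symmetric in the two depths) or ``"focal"`` (the
    focal dive's own depth).
    """
    if not max_depth_m > 0:
        raise ValidationError("max_depth_m must be > 0")
    if ratio_denominator not in {"max", "focal"}:
        raise ValidationError("ratio_denominator must be 'max' or 'focal'")
    for nbr in (prev_max_depth_m, next_max_depth_m):
        if nbr is None or not np.isfinite(nbr):
            continue
        denom = max(max_depth_m, nbr) if ratio_denominator == "max" else max_depth_m
        if abs(max_depth_m - nbr) <= NEIGHBOUR_TOLERANCE * denom:
            return "benthic", "consecutive_10pct"
    if seafloor_depth_m < SHALLOW_BATHY_M:
        return "benthic", "shallow_bathy"
    if abs(max_depth_m - seafloor_depth_m) < DEPTH_VS_BATHY_M:
        return "benthic", "depth_vs_bathy"
    return "pelagic", "none"


@dataclass
class ClassificationSummary:
    n_dives: int
    n_classified: int
    n_unclassifiable: int
    benthic_fraction: float
    per_trip_pelagic_pct: pd.DataFrame


def locate_dives(dive_table: pd.DataFrame, track: pd.DataFrame,
                 gps_interval_s: float | None = None) -> pd.DataFrame:
    """Attach interpolated lon/lat (at dive start) to a dive table.

    Dives outside the track span get NaN positions and ``low_confidence``
    True. Location at the dive start instant is a convention choice; see
    module docs.
    """
    out = dive_table.copy()
    lons, lats, flags = [], [], []
    for t in out["start"]:
        try:
            lon, lat, low = interpolate_dive_location(track, t,
                                                      gps_interval_s=gps_interval_s)
        except OutOfRangeError:
            lon, lat, low = np.nan, np.nan, True
        lons.append(lon)
        lats.append(lat)
        flags.append(low)
    out["lon"] = lons
    out["lat"] = lats
    out["low_confidence"] = flags
    return out


def classify_deployment(dive_table: pd.DataFrame, track: pd.DataFrame,
                        bathymetry: BathymetryGrid,
                        trip_ids: pd.Series | None = None,
                        gps_interval_s: float | None = None,
                        ratio_denominator: str = "max"
                        ) -> tuple[pd.DataFrame, ClassificationSummary]:
    """Locate, look up seafloor depth, and classify every dive of a deployment.

    ``trip_ids`` (aligned with ``dive_table``) restricts the neighbour
    criterion to dives of the same trip; dives with a null trip id have no
    neighbours. Returns the augmented dive table and a summary with overall
    benthic fraction and per-trip pelagic percentages.
    """
    located = locate_dives(dive_table, track, gps_interval_s=gps_interval_s)
    if trip_ids is None:
        trip_ids = pd.Series(["_all"] * len(located), index=located.index)
    else:
        trip_ids = trip_ids.reindex(located.index)
    seafloor = np.atleast_1d(bathymetry.depth_at(located["lon"].to_numpy(),
                                                 located["lat"].to_numpy())) \
        if len(located) else np.array([])
    located["seafloor_m"] = seafloor if len(located) else np.nan
    located["trip_id"] = trip_ids.to_numpy() if len(located) else []

    classes, criteria = [], []
    depths = located["max_depth_m"].to_numpy(dtype=float)
    tids = located["trip_id"].to_numpy()
    def _same_trip(a, b):
        return not pd.isna(a) and not pd.isna(b) and a == b

    for i in range(len(located)):
        sf = located["seafloor_m"].iloc[i]
        if not np.isfinite(sf):
            classes.append("unclassifiable")
            criteria.append("none")
            continue
        prev_d = depths[i - 1] if i > 0 and _same_trip(tids[i - 1], tids[i]) else None
        next_d = depths[i + 1] if i + 1 < len(located) and _same_trip(tids[i + 1], tids[i]) else None
        cls, crit = classify_dive(depths[i], prev_d, next_d, sf,
                                  ratio_denominator=ratio_denominator)
        classes.append(cls)
        criteria.append(crit)
    located["dive_class"] = classes
    located["criterion"] = criteria

    ok = located[located["dive_class"] != "unclassifiable"]
    benthic_frac = float((ok["dive_class"] == "benthic").mean()) if len(ok) else np.nan
    per_trip = (ok.groupby("trip_id")["dive_class"]
                .apply(lambda s: 100.0 * float((s == "pelagic").mean()))
                .rename("pelagic_pct").reset_index()) if len(ok) else \
        pd.DataFrame(columns=["trip_id", "pelagic_pct"])
    summary = ClassificationSummary(
        n_dives=len(located),
        n_classified=len(ok),
        n_unclassifiable=int((located["dive_class"] == "unclassifiable").sum()),
        benthic_fraction=benthic_frac,
        per_trip_pelagic_pct=per_trip,
    )
    return located, summary


def assign_trip_ids(dive_table: pd.DataFrame, trips) -> pd.Series:
    """Map each dive (by start time) to the trip whose span contains it.

    ``trips`` is a list of :class:`divekit.trips.Trip`. Dives outside every
    trip get pd.NA.
    """
    ids = []
    for t in dive_table["start"]:
        hit = pd.NA
        for trip in trips:
            if trip.departure_time <= t <= trip.return_time:
                hit = trip.trip_id
                break
        ids.append(hit)
    return pd.Series(ids, index=dive_table.index, dtype="object")
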