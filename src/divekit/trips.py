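"""Split GPS tracks into foraging trips around a colony buffer.

A trip runs from the last fix inside the colony buffer before an excursion
to the first fix back inside it. A fix at exactly the buffer distance counts
as inside (ties break toward the colony), so zero-length trips cannot occur.
Departure and return instants are refined by linear interpolation of the
colony distance between the bracketing fixes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import solar
from .errors import ValidationError
from .geo import haversine_m

DEFAULT_BUFFER_M = 500.0
DEFAULT_ROOST_WINDOW_H = 2.0
DEFAULT_ROOST_DISPLACEMENT_M = 200.0


@dataclass
class Trip:
    """One colony departure-to-return excursion."""

    trip_id: int
    fixes: pd.DataFrame = field(repr=False)  # timestamp, lon, lat (+ colony_dist_m)
    departure_time: pd.Timestamp
    return_time: pd.Timestamp
    complete: bool
    total_distance_km: float = np.nan
    max_distance_km: float = np.nan
    overnight_roost: bool = False

    @property
    def duration_h(self) -> float:
        return (self.return_time - self.departure_time).total_seconds() / 3600.0


def split_trips(track: pd.DataFrame, colony_lonlat: tuple[float, float],
                buffer_m: float = DEFAULT_BUFFER_M) -> list[Trip]:
    """Segment a sorted single-individual track into trips.

    A track that never leaves the buffer yields zero trips. Excursions that
    are still in progress when the record starts or ends are returned with
    ``complete=False``; their missing edge time is the first/last observed
    fix time.
    """
    if buffer_m <= 0:
        raise ValidationError("buffer_m must be > 0")
    if len(track) == 0:
        return []
    ts = track["timestamp"].reset_index(drop=True)
    if not ts.is_monotonic_increasing:
        raise ValidationError("track must be sorted by timestamp")
    lon = track["lon"].to_numpy(dtype=float)
    lat = track["lat"].to_numpy(dtype=float)
    dist = np.atleast_1d(haversine_m(lon, lat, colony_lonlat[0], colony_lonlat[1]))
    inside = dist <= buffer_m

    trips: list[Trip] = []
    n = len(inside)
    i = 0
    trip_id = 0
    while i < n:
        if inside[i]:
            i += 1
            continue
        # excursion: run of outside fixes [i, j]
        j = i
        while j + 1 < n and not inside[j + 1]:
            j += 1
        lead = i - 1 if i > 0 else None     # last inside fix before
        trail = j + 1 if j + 1 < n else None  # first inside fix after
        lo = lead if lead is not None else i
        hi = trail if trail is not None else j
        fixes = track.iloc[lo:hi + 1].copy().reset_index(drop=True)
        fixes["colony_dist_m"] = dist[lo:hi + 1]
        if lead is not None:
            departure = _crossing_time(ts[lead], dist[lead], ts[i], dist[i], buffer_m)
        else:
            departure = ts[i]
        if trail is not None:
            ret = _crossing_time(ts[j], dist[j], ts[trail], dist[trail], buffer_m)
        else:
            ret = ts[j]
        trip = Trip(trip_id=trip_id, fixes=fixes, departure_time=departure,
                    return_time=ret, complete=lead is not None and trail is not None)
        trip_stats(trip, colony_lonlat)
        trips.append(trip)
        trip_id += 1
        i = j + 1
    return trips


def _crossing_time(t0, d0, t1, d1, buffer_m):
    """Linear interpolation of the instant the colony distance crosses the buffer."""
    if d1 == d0:
        return t0
    frac = float(np.clip((buffer_m - d0) / (d1 - d0), 0.0, 1.0))
    return t0 + (t1 - t0) * frac


def trip_stats(trip: Trip, colony_lonlat: tuple[float, float]) -> tuple[float, float, float]:
    """Compute (duration_h, total_distance_km, max_distance_km) and store them.

    Total distance sums consecutive-fix great-circle legs; max distance is
    the largest fix-to-colony distance. Stats are computed for incomplete
    trips too — callers should exclude those from duration summaries.
    """
    lon = trip.fixes["lon"].to_numpy(dtype=float)
    lat = trip.fixes["lat"].to_numpy(dtype=float)
    if len(lon) > 1:
        legs = haversine_m(lon[:-1], lat[:-1], lon[1:], lat[1:])
        total = float(np.sum(legs))
    else:
        total = 0.0
    dist = np.atleast_1d(haversine_m(lon, lat, colony_lonlat[0], colony_lonlat[1]))
    trip.total_distance_km = total / 1000.0
    trip.max_distance_km = float(np.max(dist)) / 1000.0
    return trip.duration_h, trip.total_distance_km, trip.max_distance_km


def detect_overnight_roost(trip: Trip, colony_lonlat: tuple[float, float],
                           tz_offset_h: float,
                           buffer_m: float = DEFAULT_BUFFER_M,
                           window_h: float = DEFAULT_ROOST_WINDOW_H,
                           max_displacement_m: float = DEFAULT_ROOST_DISPLACEMENT_M) -> bool:
    """Flag a trip as containing an overnight roost away from the colony.

    True iff the trip spans at least one local midnight while outside the
    colony buffer AND some night-time (sun below horizon) window of at least
    ``window_h`` hours shows a net displacement under ``max_displacement_m``.
    The stationarity thresholds are study choices, not measurements, and are
    configurable.
    """
    off = pd.Timedelta(hours=tz_offset_h)
    dep_local = trip.departure_time + off
    ret_local = trip.return_time + off
    if ret_local.normalize() <= dep_local.normalize():
        trip.overnight_roost = False
        return False
    fx = trip.fixes
    out_mask = fx["colony_dist_m"].to_numpy() > buffer_m
    elev = solar.solar_elevation_deg(fx["timestamp"], fx["lon"].to_numpy(),
                                     fx["lat"].to_numpy())
    night = np.atleast_1d(elev) < 0.0
    cand = night & out_mask
    ts = fx["timestamp"].reset_index(drop=True)
    lon = fx["lon"].to_numpy(dtype=float)
    lat = fx["lat"].to_numpy(dtype=float)
    n = len(fx)
    win_s = window_h * 3600.0
    tsec = (ts - ts.iloc[0]).dt.total_seconds().to_numpy()
    for i in range(n):
        if not cand[i]:
            continue
        j = int(np.searchsorted(tsec, tsec[i] + win_s))
        if j >= n or not cand[i:j + 1].all():
            continue
        if haversine_m(lon[i], lat[i], lon[j], lat[j]) < max_displacement_m:
            trip.overnight_roost = True
            return True
    trip.overnight_roost = False
    return False


def trips_table(trips: list[Trip], individual_id: str = "",
                sex: str = "unknown") -> pd.DataFrame:
    """Flatten Trip objects into the trip CSV schema."""
    rows = [{
        "trip_id": f"{individual_id}_t{t.trip_id}" if individual_id else t.trip_id,
        "individual_id": individual_id,
        "sex": sex,
        "departure_time": t.departure_time,
        "return_time": t.return_time,
        "duration_h": t.duration_h,
        "total_distance_km": t.total_distance_km,
        "max_distance_km": t.max_distance_km,
        "complete": t.complete,
        "overnight_roost": t.overnight_roost,
    } for t in trips]
    return pd.DataFrame(rows, columns=["trip_id", "individual_id", "sex",
                                       "departure_time", "return_time",
                                       "duration_h", "total_distance_km",
                                       "max_distance_km", "complete",
                                       "overnight_roost"])


def departure_return_histograms(trip_table: pd.DataFrame,
                                tz_offset_h: float) -> pd.DataFrame:
    """24-bin local-hour counts of departures and returns, per sex.

    Only complete trips are counted. Returns a tidy frame with columns
    sex, hour, departures, returns.
    """
    if len(trip_table) == 0:
        raise ValidationError("need at least one trip")
    df = trip_table[trip_table["complete"]].copy()
    off = pd.Timedelta(hours=tz_offset_h)
    df["dep_hour"] = (df["departure_time"] + off).dt.hour
    df["ret_hour"] = (df["return_time"] + off).dt.hour
    rows = []
    for sex, grp in df.groupby("sex"):
        dep = grp["dep_hour"].value_counts()
        ret = grp["ret_hour"].value_counts()
        for hour in range(24):
            rows.append({"sex": sex, "hour": hour,
                         "departures": int(dep.get(hour, 0)),
                         "returns": int(ret.get(hour, 0))})
    return pd.DataFrame(rows, columns=["sex", "hour", "departures", "returns"])
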