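"""Hourly dive-rate effort index and day/night flags.

Dive rate is the vertical distance travelled per hour of observed record
time (m/h), tabulated by local clock hour. Dives spanning an hour boundary
are assigned to the hour of their midpoint; hours with zero observed record
time are excluded rather than zero-filled.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import solar


def _hour_coverage_s(start: pd.Timestamp, end: pd.Timestamp,
                     tz_offset_h: float) -> dict[int, float]:
    """Seconds of each local clock hour covered by [start, end]."""
    off = pd.Timedelta(hours=tz_offset_h)
    s = start + off
    e = end + off
    cover: dict[int, float] = {}
    cur = s
    while cur < e:
        nxt = min((cur + pd.Timedelta(hours=1)).floor("h"), e)
        cover[cur.hour] = cover.get(cur.hour, 0.0) + (nxt - cur).total_seconds()
        cur = nxt
    return cover


def hourly_dive_rate(dive_table: pd.DataFrame,
                     record_start: pd.Timestamp, record_end: pd.Timestamp,
                     tz_offset_h: float,
                     individual_id: str = "", sex: str = "unknown") -> pd.DataFrame:
    """Per-local-hour dive rate (m vertical distance per observed hour).

    Returns columns individual_id, sex, hour, dive_rate_m_per_h,
    record_hours. Covered hours with no dives appear with rate 0.
    """
    cover = _hour_coverage_s(record_start, record_end, tz_offset_h)
    vdist: dict[int, float] = {h: 0.0 for h in cover}
    if len(dive_table):
        mid = dive_table["start"] + (dive_table["end"] - dive_table["start"]) / 2
        hours = (mid + pd.Timedelta(hours=tz_offset_h)).dt.hour
        for h, v in zip(hours, dive_table["vertical_distance_m"]):
            vdist[int(h)] = vdist.get(int(h), 0.0) + float(v)
    rows = []
    for h in sorted(cover):
        secs = cover[h]
        if secs <= 0:
            continue
        rows.append({"individual_id": individual_id, "sex": sex, "hour": h,
                     "dive_rate_m_per_h": vdist.get(h, 0.0) / (secs / 3600.0),
                     "record_hours": secs / 3600.0})
    return pd.DataFrame(rows, columns=["individual_id", "sex", "hour",
                                       "dive_rate_m_per_h", "record_hours"])


def daylight_flags(times, lon, lat) -> np.ndarray:
    """True where the sun is above the horizon at each instant/location."""
    return np.atleast_1d(solar.is_daylight(times, lon, lat))


def plot_hourly_effort(effort: pd.DataFrame, path) -> None:
    """Hourly mean +/- SE dive rate by sex (the tidy table a GAMM would consume)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for sex, grp in effort.groupby("sex"):
        agg = grp.groupby("hour")["dive_rate_m_per_h"].agg(["mean", "sem"])
        ax.errorbar(agg.index, agg["mean"], yerr=agg["sem"], label=sex,
                    marker="o", capsize=2)
    ax.set_xlabel("local hour of day")
    ax.set_ylabel("dive rate (m/h)")
    ax.set_xticks(range(0, 24, 3))
    ax.legend(title="sex")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
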