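"""Dive detection and per-dive summary statistics from 4-s depth records.

The workflow is: zero-offset correction of sensor drift, threshold
segmentation into dives, refinement of dive edges by extrapolating the line
through the first/last two in-dive samples to its zero-depth crossing, then
summary statistics (maximum depth, duration, vertical distance) and
post-dive surface intervals.

Because depth is only sampled every ``pressure_interval_s`` seconds, both
maximum depth and vertical distance are systematically underestimated for
real dives; no correction is attempted.

The detection threshold defaults to 1 m. For shallow divers this choice is
consequential — a lower threshold admits more of the shallow dive tail but
also more surface noise — so it is exposed everywhere as ``min_depth_m``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import IntegrityError, ValidationError

DEFAULT_MIN_DEPTH_M = 1.0
DEFAULT_ZOC_WINDOW_S = 7200.0
DEFAULT_ZOC_QUANTILE = 0.05


@dataclass
class Dive:
    """One detected dive with raw sample span and interpolated edges."""

    dive_id: int
    times: np.ndarray = field(repr=False)   # in-dive sample times, seconds from record start
    depths: np.ndarray = field(repr=False)  # in-dive depths, m
    prev_surface_s: float | None            # time of last surface sample before the dive
    next_surface_s: float | None            # time of first surface sample after the dive
    sample_interval_s: float
    start_s: float = np.nan                 # interpolated edge times
    end_s: float = np.nan
    edge_fallback: bool = False             # True when edges fell back to raw span

    @property
    def raw_first_s(self) -> float:
        return float(self.times[0])

    @property
    def raw_last_s(self) -> float:
        return float(self.times[-1])

    @property
    def max_depth_m(self) -> float:
        return float(np.max(self.depths))

    @property
    def duration_s(self) -> float:
        return float(self.end_s - self.start_s)

    @property
    def vertical_distance_m(self) -> float:
        """Sum of |depth change| over in-dive samples plus the two edge legs.

        The edge legs are the descents from/to the surface: first-sample depth
        plus last-sample depth.
        """
        d = self.depths
        return float(d[0] + np.sum(np.abs(np.diff(d))) + d[-1])


def zero_offset_correct(series: pd.DataFrame,
                        window_s: float = DEFAULT_ZOC_WINDOW_S,
                        quantile: float = DEFAULT_ZOC_QUANTILE) -> pd.DataFrame:
    """Remove surface drift by subtracting a rolling lower-quantile baseline.

    A centred rolling window of ``window_s`` seconds is passed over the depth
    record; its ``quantile`` (default 5th percentile) estimates the
    instantaneous surface reading, which is subtracted and the result clipped
    at 0. Idempotent on records whose windows always contain some surface time.
    """
    if len(series) == 0:
        raise ValidationError("cannot zero-offset-correct an empty series")
    if window_s <= 0:
        raise ValidationError("window_s must be > 0")
    s = series.set_index("timestamp")["depth_m"]
    baseline = s.rolling(f"{int(window_s)}s", min_periods=1, center=True).quantile(quantile)
    corrected = (s - baseline).clip(lower=0.0)
    out = series.copy()
    out["depth_m"] = corrected.to_numpy()
    return out


def detect_dives(series: pd.DataFrame,
                 min_depth_m: float = DEFAULT_MIN_DEPTH_M) -> list[Dive]:
    """Segment a corrected depth record into dives.

    A dive is a maximal run of consecutive samples with depth strictly greater
    than ``min_depth_m``. Single-sample dives are retained (discarding them
    would bias the shallow tail). Edges are refined in the same pass via
    :func:`interpolate_dive_edges`.
    """
    if min_depth_m <= 0:
        raise ValidationError("min_depth_m must be > 0")
    t = _seconds_from_start(series)
    d = series["depth_m"].to_numpy(dtype=float)
    wet = d > min_depth_m
    if not wet.any():
        return []
    edges = np.diff(wet.astype(np.int8))
    starts = np.nonzero(edges == 1)[0] + 1
    ends = np.nonzero(edges == -1)[0]
    if wet[0]:
        starts = np.concatenate(([0], starts))
    if wet[-1]:
        ends = np.concatenate((ends, [len(d) - 1]))
    interval = _median_interval(t)
    dives = []
    for k, (i, j) in enumerate(zip(starts, ends)):
        dive = Dive(
            dive_id=k,
            times=t[i:j + 1].copy(),
            depths=d[i:j + 1].copy(),
            prev_surface_s=float(t[i - 1]) if i > 0 else None,
            next_surface_s=float(t[j + 1]) if j + 1 < len(t) else None,
            sample_interval_s=interval,
        )
        interpolate_dive_edges(dive)
        dives.append(dive)
    return dives


def interpolate_dive_edges(dive: Dive) -> tuple[float, float]:
    """Refine dive start/end to the zero-depth crossings of the edge lines.

    The start is where the line through the first two in-dive samples crosses
    depth 0, clamped to [previous surface sample time, first in-dive sample
    time]; the end is symmetric with the last two samples. Single-sample
    dives fall back to the raw sample time ± half the sampling interval and
    are flagged.
    """
    t, d = dive.times, dive.depths
    half = dive.sample_interval_s / 2.0
    lo = dive.prev_surface_s if dive.prev_surface_s is not None else t[0] - half
    hi = dive.next_surface_s if dive.next_surface_s is not None else t[-1] + half
    if len(t) < 2:
        dive.start_s = max(float(t[0] - half), lo)
        dive.end_s = min(float(t[0] + half), hi)
        dive.edge_fallback = True
        return dive.start_s, dive.end_s
    # descent line through first two samples
    if d[1] > d[0]:
        slope = (d[1] - d[0]) / (t[1] - t[0])
        start = t[0] - d[0] / slope
    else:
        start = lo  # flat or inverted edge: clamp to previous surface sample
    dive.start_s = float(np.clip(start, lo, t[0]))
    # ascent line through last two samples
    if d[-2] > d[-1]:
        slope = (d[-2] - d[-1]) / (t[-1] - t[-2])
        end = t[-1] + d[-1] / slope
    else:
        end = hi
    dive.end_s = float(np.clip(end, t[-1], hi))
    return dive.start_s, dive.end_s


def summarize_dive(dive: Dive) -> tuple[float, float, float]:
    """(max_depth_m, duration_s, vertical_distance_m) for one dive."""
    return dive.max_depth_m, dive.duration_s, dive.vertical_distance_m


def post_dive_intervals(dives: list[Dive]) -> list[float]:
    """Surface interval after each dive; the last dive has none.

    ``interval[i] = start[i+1] - end[i]`` using interpolated edges. Raises
    :class:`IntegrityError` if dives overlap.
    """
    intervals = []
    for cur, nxt in zip(dives, dives[1:]):
        gap = nxt.start_s - cur.end_s
        if gap < 0:
            raise IntegrityError(
                f"dives {cur.dive_id} and {nxt.dive_id} overlap ({gap:.3f} s)")
        intervals.append(float(gap))
    return intervals


def extract_dives(series: pd.DataFrame,
                  min_depth_m: float = DEFAULT_MIN_DEPTH_M,
                  zoc: bool = True,
                  zoc_window_s: float = DEFAULT_ZOC_WINDOW_S,
                  zoc_quantile: float = DEFAULT_ZOC_QUANTILE) -> pd.DataFrame:
    """Full extraction: ZOC, detection, edge refinement, summaries.

    Returns a dive table with one row per dive:
    dive_id, start, end, duration_s, max_depth_m, vertical_distance_m,
    post_dive_s (NaN for the last dive), edge_fallback.
    """
    corrected = zero_offset_correct(series, zoc_window_s, zoc_quantile) if zoc else series
    dives = detect_dives(corrected, min_depth_m)
    t0 = series["timestamp"].iloc[0]
    intervals = post_dive_intervals(dives) + [np.nan] if dives else []
    rows = []
    for dive, pdi in zip(dives, intervals):
        rows.append({
            "dive_id": dive.dive_id,
            "start": t0 + pd.Timedelta(seconds=dive.start_s),
            "end": t0 + pd.Timedelta(seconds=dive.end_s),
            "duration_s": dive.duration_s,
            "max_depth_m": dive.max_depth_m,
            "vertical_distance_m": dive.vertical_distance_m,
            "post_dive_s": pdi,
            "edge_fallback": dive.edge_fallback,
        })
    return pd.DataFrame(rows, columns=["dive_id", "start", "end", "duration_s",
                                       "max_depth_m", "vertical_distance_m",
                                       "post_dive_s", "edge_fallback"])


def _seconds_from_start(series: pd.DataFrame) -> np.ndarray:
    ts = series["timestamp"]
    return (ts - ts.iloc[0]).dt.total_seconds().to_numpy(dtype=float)


def _median_interval(t: np.ndarray) -> float:
    if len(t) < 2:
        return 4.0
    return float(np.median(np.diff(t)))
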