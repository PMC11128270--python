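"""Readers and writers for the plain-text formats the pipeline exchanges.

Tracks, pressure records and diet tables travel as CSV; bathymetry travels
as an ESRI ASCII grid (optionally with a ``.prj`` sidecar). All timestamps
are stored timezone-aware in UTC; local clock time only ever appears in
derived hour-of-day outputs.

CSV dialects
------------
track     : individual_id,timestamp,lon,lat
pressure  : individual_id,timestamp,depth_m
diet      : sample_id,individual_id,sex,year,species,count,length_cm,identifiable
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (FormatError, IntegrityError, UnsupportedCRSError,
                     ValidationError)

TRACK_COLUMNS = ["individual_id", "timestamp", "lon", "lat"]
PRESSURE_COLUMNS = ["individual_id", "timestamp", "depth_m"]
DIET_COLUMNS = ["sample_id", "individual_id", "sex", "year",
                "species", "count", "length_cm", "identifiable"]

TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M:%S.%f%z"


# ---------------------------------------------------------------------------
# tabular readers/writers


def _parse_timestamps(raw: pd.Series, path) -> pd.Series:
    try:
        ts = pd.to_datetime(raw, format="ISO8601", utc=False)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: unparseable timestamp ({exc})") from None
    if ts.dt.tz is None:
        raise FormatError(f"{path}: timestamps must be timezone-aware ISO-8601")
    return ts.dt.tz_convert("UTC")


def _read_timeseries_csv(path, value_cols: list[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype={"individual_id": str})
    required = ["individual_id", "timestamp", *value_cols]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    df = df[required].copy()
    df["timestamp"] = _parse_timestamps(df["timestamp"], path)
    for col in value_cols:
        if not np.issubdtype(df[col].dtype, np.number):
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError):
                raise FormatError(f"{path}: non-numeric value in column '{col}'") from None
        if df[col].isna().any():
            raise FormatError(f"{path}: missing value in column '{col}'")
    df = df.sort_values(["individual_id", "timestamp"], kind="mergesort")
    dup = df.duplicated(subset=["individual_id", "timestamp"])
    if dup.any():
        t = df.loc[dup, "timestamp"].iloc[0]
        raise IntegrityError(f"{path}: duplicate timestamp {t} within an individual")
    return df.reset_index(drop=True)


def read_track_csv(path) -> pd.DataFrame:
    """Read a GPS track CSV into a sorted, validated DataFrame.

    Raises :class:`FormatError` for missing/malformed columns and
    :class:`IntegrityError` for duplicate timestamps within an individual.
    """
    df = _read_timeseries_csv(path, ["lon", "lat"])
    bad_lon = ~df["lon"].between(-180.0, 180.0)
    bad_lat = ~df["lat"].between(-90.0, 90.0)
    if bad_lon.any() or bad_lat.any():
        raise FormatError(f"{path}: coordinate outside valid lon/lat range")
    return df


def read_pressure_csv(path) -> pd.DataFrame:
    """Read a pressure/depth record CSV (depths in metres, positive down)."""
    return _read_timeseries_csv(path, ["depth_m"])


def _write_timeseries_csv(df: pd.DataFrame, path, value_cols: list[str]) -> None:
    out = df.copy()
    out["timestamp"] = out["timestamp"].dt.strftime(TIMESTAMP_FORMAT)
    out[["individual_id", "timestamp", *value_cols]].to_csv(
        path, index=False, float_format="%.8f")


def write_track_csv(df: pd.DataFrame, path) -> None:
    _write_timeseries_csv(df, path, ["lon", "lat"])


def write_pressure_csv(df: pd.DataFrame, path) -> None:
    _write_timeseries_csv(df, path, ["depth_m"])


def read_diet_csv(path) -> pd.DataFrame:
    """Read a diet item table; one row per (sample, prey item record).

    Samples with no identifiable remains carry ``identifiable=False`` and an
    empty species field.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"sample_id": str, "individual_id": str,
                                  "sex": str, "species": str})
    for col in DIET_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    df = df[DIET_COLUMNS].copy()
    df["identifiable"] = df["identifiable"].astype(bool)
    ident = df["identifiable"]
    if (ident & (df["species"].isna() | (df["species"] == ""))).any():
        raise FormatError(f"{path}: identifiable row without a species")
    if (ident & (pd.to_numeric(df["count"], errors="coerce") < 1)).any():
        raise IntegrityError(f"{path}: prey item with count < 1")
    return df


def write_diet_csv(df: pd.DataFrame, path) -> None:
    df[DIET_COLUMNS].to_csv(path, index=False, float_format="%.4f")


# ---------------------------------------------------------------------------
# bathymetry


@dataclass
class BathymetryGrid:
    """Regular lon/lat grid of seafloor depth, metres positive-down.

    ``values[row, col]`` is indexed with latitude increasing with ``row``
    (row 0 is the southernmost row). ``x0``/``y0`` are the lower-left corner
    of the grid, ``cell_size`` is in decimal degrees.
    """

    x0: float
    y0: float
    cell_size: float
    values: np.ndarray  # shape (n_rows, n_cols), depth >= 0
    n_land_clamped: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("bathymetry values must be a 2-D array")
        if self.cell_size <= 0:
            raise ValidationError("bathymetry cell_size must be > 0")
        if np.isnan(self.values).any():
            raise ValidationError("bathymetry contains missing cells")
        if (self.values < 0).any():
            raise ValidationError("bathymetry depth must be >= 0 (positive down)")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(lon_min, lon_max, lat_min, lat_max) of the grid outline."""
        return (self.x0, self.x0 + self.n_cols * self.cell_size,
                self.y0, self.y0 + self.n_rows * self.cell_size)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        cs = self.cell_size
        lons = self.x0 + (np.arange(self.n_cols) + 0.5) * cs
        lats = self.y0 + (np.arange(self.n_rows) + 0.5) * cs
        return lons, lats

    def contains(self, lon, lat) -> np.ndarray:
        x0, x1, y0, y1 = self.extent
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (lon >= x0) & (lon <= x1) & (lat >= y0) & (lat <= y1)

    def depth_at(self, lon, lat):
        """Bilinear-interpolated depth at lon/lat; NaN outside the grid."""
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        cs = self.cell_size
        # continuous cell-centre coordinates
        fx = (lon - self.x0) / cs - 0.5
        fy = (lat - self.y0) / cs - 0.5
        # clamp to the centre lattice so edge half-cells extrapolate flat
        fx_c = np.clip(fx, 0.0, self.n_cols - 1.0)
        fy_c = np.clip(fy, 0.0, self.n_rows - 1.0)
        ix = np.clip(np.floor(fx_c).astype(int), 0, self.n_cols - 2) \
            if self.n_cols > 1 else np.zeros_like(fx_c, dtype=int)
        iy = np.clip(np.floor(fy_c).astype(int), 0, self.n_rows - 2) \
            if self.n_rows > 1 else np.zeros_like(fy_c, dtype=int)
        tx = fx_c - ix if self.n_cols > 1 else np.zeros_like(fx_c)
        ty = fy_c - iy if self.n_rows > 1 else np.zeros_like(fy_c)
        v = self.values
        jx = np.minimum(ix + 1, self.n_cols - 1)
        jy = np.minimum(iy + 1, self.n_rows - 1)
        out = ((1 - tx) * (1 - ty) * v[iy, ix] + tx * (1 - ty) * v[iy, jx]
               + (1 - tx) * ty * v[jy, ix] + tx * ty * v[jy, jx])
        out = np.where(self.contains(lon, lat), out, np.nan)
        return out if out.size > 1 else float(out[0])


def read_bathymetry(path) -> BathymetryGrid:
    """Read an ESRI ASCII grid of elevations into a positive-down depth grid.

    Negative elevations (below sea level) become positive depths; cells at or
    above sea level are clamped to depth 0 and counted in
    :attr:`BathymetryGrid.n_land_clamped` (a warning is emitted when > 0).
    A ``.prj`` sidecar describing a projected CRS raises
    :class:`UnsupportedCRSError`; only geographic lon/lat rasters are handled.
    """
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        raise FormatError(
            f"{path}: GeoTIFF input is not supported in this build; "
            "convert to ESRI ASCII grid (.asc)")
    prj = path.with_suffix(".prj")
    if prj.exists():
        text = prj.read_text()
        if "PROJCS" in text.upper():
            raise UnsupportedCRSError(
                f"{prj}: projected CRS rasters are unsupported; supply lon/lat")
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value"}:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise FormatError(f"{path}: missing ESRI ASCII header field '{key}'")
    if header["cellsize"] <= 0:
        raise FormatError(f"{path}: cellsize must be > 0")
    data = np.loadtxt(lines[n_header:], dtype=float)
    data = np.atleast_2d(data)
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise FormatError(
            f"{path}: data shape {data.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})")
    nodata = header.get("nodata_value")
    if nodata is not None and (data == nodata).any():
        raise FormatError(f"{path}: NODATA cells inside declared extent")
    elevation = data[::-1, :]  # file rows run north->south
    depth = -elevation
    n_land = int((depth < 0).sum())
    depth = np.clip(depth, 0.0, None)
    if n_land:
        warnings.warn(f"{path}: {n_land} land cells clamped to depth 0",
                      stacklevel=2)
    return BathymetryGrid(x0=header["xllcorner"], y0=header["yllcorner"],
                          cell_size=header["cellsize"], values=depth,
                          n_land_clamped=n_land)


def write_bathymetry(grid: BathymetryGrid, path) -> None:
    """Write a depth grid as an ESRI ASCII elevation raster (sea negative)."""
    elevation = -grid.values[::-1, :]
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.x0:.10f}\n")
        fh.write(f"yllcorner {grid.y0:.10f}\n")
        fh.write(f"cellsize {grid.cell_size:.10f}\n")
        np.savetxt(fh, elevation, fmt="%.4f")


# ---------------------------------------------------------------------------
# deployments


@dataclass
class Deployment:
    """One instrumented individual: metadata plus its track and pressure record."""

    individual_id: str
    sex: str
    mass_kg: float
    tarsus_mm: float
    year: int
    track: pd.DataFrame = field(repr=False)
    pressure: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        if self.sex not in {"M", "F", "unknown"}:
            raise ValidationError(f"sex must be M, F or unknown, got {self.sex!r}")
        if not self.mass_kg > 0:
            raise ValidationError("mass_kg must be > 0")
        for name, df in (("track", self.track), ("pressure", self.pressure)):
            ts = df["timestamp"]
            if len(ts) and not ts.is_monotonic_increasing:
                raise ValidationError(f"{name} timestamps must be sorted")
            if ts.duplicated().any():
                raise IntegrityError(f"{name} contains duplicate timestamps")
        if len(self.track) and len(self.pressure):
            t0 = max(self.track["timestamp"].iloc[0], self.pressure["timestamp"].iloc[0])
            t1 = min(self.track["timestamp"].iloc[-1], self.pressure["timestamp"].iloc[-1])
            if t0 > t1:
                raise IntegrityError("track and pressure time ranges do not overlap")


def read_individuals_csv(path) -> pd.DataFrame:
    """Read individual metadata: individual_id,sex,mass_kg,tarsus_mm,year."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"individual_id": str, "sex": str})
    for col in ("individual_id", "sex", "mass_kg", "tarsus_mm", "year"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    if (df["mass_kg"] <= 0).any():
        raise ValidationError(f"{path}: mass_kg must be > 0")
    return df


def write_individuals_csv(df: pd.DataFrame, path) -> None:
    df[["individual_id", "sex", "mass_kg", "tarsus_mm", "year"]].to_csv(
        path, index=False, float_format="%.4f")
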