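"""Kernel utilization distributions, 95% contours and overlap indices.

The smoothing factor ``h`` follows the study convention of being expressed
in the same (unprojected decimal-degree) units as the coordinates, default
0.01. For new work a projected-metres analysis is preferable; any metric
grid can be supplied through :class:`GridSpec`, the maths below is unit
agnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box
from shapely.ops import unary_union

from .errors import GridMismatchError, InsufficientDataError, ValidationError

DEFAULT_H = 0.01
DEFAULT_GRID_CELLS = 200
MIN_POINTS = 5


@dataclass(frozen=True)
class GridSpec:
    """Regular grid: lower-left corner, square cell size, column/row counts."""

    x0: float
    y0: float
    cell_size: float
    n_cols: int
    n_rows: int

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        cs = self.cell_size
        xs = self.x0 + (np.arange(self.n_cols) + 0.5) * cs
        ys = self.y0 + (np.arange(self.n_rows) + 0.5) * cs
        return xs, ys

    def matches(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        return (self.n_cols == other.n_cols and self.n_rows == other.n_rows
                and abs(self.x0 - other.x0) <= tol
                and abs(self.y0 - other.y0) <= tol
                and abs(self.cell_size - other.cell_size) <= tol)

    @staticmethod
    def around_points(x, y, h: float, n_cells: int = DEFAULT_GRID_CELLS,
                      margin_h: float = 5.0) -> "GridSpec":
        """Square-cell grid covering the points with a ``margin_h * h`` margin."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, x1 = x.min() - margin_h * h, x.max() + margin_h * h
        y0, y1 = y.min() - margin_h * h, y.max() + margin_h * h
        cell = max(x1 - x0, y1 - y0) / n_cells
        n_cols = int(np.ceil((x1 - x0) / cell))
        n_rows = int(np.ceil((y1 - y0) / cell))
        return GridSpec(x0=x0, y0=y0, cell_size=cell, n_cols=n_cols, n_rows=n_rows)


@dataclass
class UtilizationDistribution:
    """Probability mass per grid cell; sums to 1."""

    grid: GridSpec
    masses: np.ndarray = field(repr=False)  # shape (n_rows, n_cols)
    h: float = DEFAULT_H
    n_points: int = 0

    def __post_init__(self):
        self.masses = np.asarray(self.masses, dtype=float)
        if self.masses.shape != (self.grid.n_rows, self.grid.n_cols):
            raise ValidationError("UD mass array does not match its grid")
        if (self.masses < 0).any():
            raise ValidationError("UD masses must be non-negative")
        total = self.masses.sum()
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValidationError(f"UD masses must sum to 1 (got {total:.8f})")


def fit_kde(points, h: float = DEFAULT_H,
            grid: GridSpec | None = None,
            n_cells: int = DEFAULT_GRID_CELLS) -> UtilizationDistribution:
    """Isotropic bivariate Gaussian KDE evaluated on a regular grid.

    ``points`` is an (n, 2) array of x/y coordinates. The density is
    evaluated at cell centres and normalized so cell masses sum to exactly 1.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError("points must be an (n, 2) array")
    if pts.shape[0] < MIN_POINTS:
        raise InsufficientDataError(
            f"need >= {MIN_POINTS} points for a kernel UD, got {pts.shape[0]}")
    if h <= 0:
        raise ValidationError("smoothing factor h must be > 0")
    if grid is None:
        grid = GridSpec.around_points(pts[:, 0], pts[:, 1], h, n_cells=n_cells)
    xs, ys = grid.centers()
    inv2h2 = 1.0 / (2.0 * h * h)
    density = np.zeros((grid.n_rows, grid.n_cols))
    # accumulate in chunks of points; separable exponentials keep this O(n*(nx+ny)) memory
    chunk = 512
    for i in range(0, pts.shape[0], chunk):
        px = pts[i:i + chunk, 0][:, None]
        py = pts[i:i + chunk, 1][:, None]
        ex = np.exp(-((xs[None, :] - px) ** 2) * inv2h2)  # (m, n_cols)
        ey = np.exp(-((ys[None, :] - py) ** 2) * inv2h2)  # (m, n_rows)
        density += ey.T @ ex
    total = density.sum()
    if total <= 0:
        raise ValidationError("KDE mass vanished on the supplied grid")
    return UtilizationDistribution(grid=grid, masses=density / total, h=h,
                                   n_points=pts.shape[0])


def contour_mask(ud: UtilizationDistribution, level: float = 0.95) -> np.ndarray:
    """Smallest set of cells (by descending density) holding ``level`` mass."""
    flat = ud.masses.ravel()
    order = np.argsort(flat)[::-1]
    csum = np.cumsum(flat[order])
    k = int(np.searchsorted(csum, level)) + 1
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[:min(k, flat.size)]] = True
    return mask.reshape(ud.masses.shape)


def contour_95(ud: UtilizationDistribution, level: float = 0.95):
    """(cell mask, shapely (Multi)Polygon outline) of the ``level`` home range."""
    mask = contour_mask(ud, level)
    cs = ud.grid.cell_size
    boxes = []
    rows, cols = np.nonzero(mask)
    for r, c in zip(rows, cols):
        x = ud.grid.x0 + c * cs
        y = ud.grid.y0 + r * cs
        boxes.append(box(x, y, x + cs, y + cs))
    poly = unary_union(boxes) if boxes else None
    return mask, poly


def bhattacharyya_affinity(ud_a: UtilizationDistribution,
                           ud_b: UtilizationDistribution) -> float:
    """BA = sum over cells of sqrt(p_i * q_i); 0 = disjoint, 1 = identical.

    Both UDs must live on the identical grid; no silent resampling.
    """
    if not ud_a.grid.matches(ud_b.grid):
        raise GridMismatchError("utilization distributions are on different grids")
    ba = float(np.sum(np.sqrt(ud_a.masses * ud_b.masses)))
    return min(ba, 1.0)


@dataclass
class OverlapResult:
    year: int
    ba_index: float
    ba_index_hr95: float  # BA after masking both UDs to their 95% contours
    ud_male: UtilizationDistribution
    ud_female: UtilizationDistribution
    n_male: int
    n_female: int


def _masked_ba(ud_a, ud_b, level=0.95):
    ma = contour_mask(ud_a, level)
    mb = contour_mask(ud_b, level)
    pa = np.where(ma, ud_a.masses, 0.0)
    pb = np.where(mb, ud_b.masses, 0.0)
    pa /= pa.sum()
    pb /= pb.sum()
    return float(min(np.sum(np.sqrt(pa * pb)), 1.0))


def sex_overlap_by_year(located_dives: pd.DataFrame,
                        h: float = DEFAULT_H,
                        n_cells: int = DEFAULT_GRID_CELLS,
                        margin_h: float = 5.0) -> list[OverlapResult]:
    """Male/female UD overlap per year from a located-dive table.

    ``located_dives`` needs columns lon, lat, sex, year. For each year both
    sexes' dive locations are pooled into one UD per sex on a shared grid
    and the Bhattacharyya affinity computed; years missing a sex (or with
    < 5 points for one) are skipped with a warning. Pooling across
    individuals is this implementation's convention (per-individual UDs
    averaged first is a reasonable alternative).
    """
    results = []
    df = located_dives.dropna(subset=["lon", "lat"])
    for year, grp in df.groupby("year"):
        males = grp[grp["sex"] == "M"]
        females = grp[grp["sex"] == "F"]
        if len(males) < MIN_POINTS or len(females) < MIN_POINTS:
            warnings.warn(f"year {year}: need >= {MIN_POINTS} dive locations "
                          f"per sex (M={len(males)}, F={len(females)}); skipped",
                          stacklevel=2)
            continue
        allpts = grp[["lon", "lat"]].to_numpy(dtype=float)
        grid = GridSpec.around_points(allpts[:, 0], allpts[:, 1], h,
                                      n_cells=n_cells, margin_h=margin_h)
        ud_m = fit_kde(males[["lon", "lat"]].to_numpy(dtype=float), h=h, grid=grid)
        ud_f = fit_kde(females[["lon", "lat"]].to_numpy(dtype=float), h=h, grid=grid)
        results.append(OverlapResult(
            year=int(year),
            ba_index=bhattacharyya_affinity(ud_m, ud_f),
            ba_index_hr95=_masked_ba(ud_m, ud_f),
            ud_male=ud_m, ud_female=ud_f,
            n_male=len(males), n_female=len(females)))
    return results


def polygon_to_geojson(poly, path, properties: dict | None = None) -> None:
    """Write a shapely geometry as a single-feature GeoJSON file."""
    import json

    from shapely.geometry import mapping
    feature = {"type": "Feature", "properties": properties or {},
               "geometry": mapping(poly)}
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": [feature]}, fh)
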