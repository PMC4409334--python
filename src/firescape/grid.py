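"""Grid geometry, raster containers and harmonisation operators.

All analysis happens on one abstract equal-area grid: square cells of
``cell_size`` km, row 0 at the top, 0-based row-major indexing, cell
centers at ``origin + ((col + 0.5), -(row + 0.5)) * cell_size``.  Real-world
reprojection is a preprocessing responsibility; the operators here only
guarantee alignment, resampling and derived layers on that grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from firescape.errors import (
    AlignmentError,
    CoverageError,
    DomainError,
    KindError,
    NoSourceError,
    SizeError,
)

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"
BINARY = "binary"

#: Sentinel aspect value for flat cells (zero gradient).
FLAT_ASPECT = -1.0


@dataclass(frozen=True)
class GridGeometry:
    """Geometry of a regular equal-area grid.

    Parameters
    ----------
    n_rows, n_cols
        Grid shape; both at least 1.
    cell_size
        Cell edge length in km (> 0).
    origin
        Projected (x, y) of the outer corner of the top-left cell, in km.
        x grows eastward with columns; y grows northward, i.e. decreases
        with rows.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) center coordinate vectors for columns and rows."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = y0 - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return xs, ys

    def locate(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map projected (x, y) km to (row, col); returns in-grid mask too."""
        x0, y0 = self.origin
        col = np.floor((np.asarray(x, dtype=float) - x0) / self.cell_size).astype(int)
        row = np.floor((y0 - np.asarray(y, dtype=float)) / self.cell_size).astype(int)
        inside = (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)
        return row, col, inside


@dataclass
class Raster:
    """A single-band raster bound to a :class:`GridGeometry`.

    ``kind`` is one of ``continuous``, ``categorical``, ``binary``.
    Continuous rasters use NaN as nodata by default; integer-valued kinds
    use an explicit sentinel.
    """

    geometry: GridGeometry
    values: np.ndarray
    kind: str = CONTINUOUS
    nodata: float = np.nan
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.geometry.shape:
            raise AlignmentError(
                f"values shape {self.values.shape} != geometry {self.geometry.shape}"
            )
        if self.kind not in (CONTINUOUS, CATEGORICAL, BINARY):
            raise KindError(f"unknown raster kind {self.kind!r}")
        if self.kind == BINARY:
            ok = np.isin(self.values, [0, 1]) | self._nodata_mask(self.values)
            if not ok.all():
                raise ValueError("binary raster may contain only {0, 1, nodata}")

    def _nodata_mask(self, arr: np.ndarray) -> np.ndarray:
        if isinstance(self.nodata, float) and np.isnan(self.nodata):
            return np.isnan(arr) if np.issubdtype(arr.dtype, np.floating) else np.zeros(arr.shape, bool)
        return arr == self.nodata

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of cells that are not nodata."""
        return ~self._nodata_mask(self.values)

    def with_values(self, values: np.ndarray, **kw) -> "Raster":
        return replace(self, values=np.asarray(values), **kw)


def _require_aligned(*rasters: Raster) -> None:
    geoms = {r.geometry for r in rasters}
    if len(geoms) > 1:
        raise AlignmentError("rasters are not on a common grid geometry")


def _ratio(a: float, b: float) -> int:
    """Integer ratio a/b or raise."""
    r = a / b
    k = int(round(r))
    if k < 1 or abs(r - k) > 1e-9:
        raise AlignmentError(f"cell sizes {a} and {b} are not integer multiples")
    return k


def resample_categorical(src: Raster, target: GridGeometry) -> Raster:
    """Majority-filter resampling of a categorical raster.

    Each target cell takes the modal category among the source cells whose
    centers fall inside it; nodata cells do not vote and all-nodata blocks
    yield nodata.  Ties break to the lowest category code so the result is
    deterministic and order-independent.
    """
    if src.kind not in (CATEGORICAL, BINARY):
        raise KindError("resample_categorical requires a categorical raster")
    if src.geometry == target:
        return src.with_values(src.values.copy())
    if src.geometry.origin != target.origin:
        raise CoverageError("source and target origins differ")
    if src.geometry.cell_size <= target.cell_size:
        k = _ratio(target.cell_size, src.geometry.cell_size)
        if (src.geometry.n_rows < target.n_rows * k) or (src.geometry.n_cols < target.n_cols * k):
            raise CoverageError("source does not cover the target extent")
        sub = src.values[: target.n_rows * k, : target.n_cols * k]
        blocks = sub.reshape(target.n_rows, k, target.n_cols, k).swapaxes(1, 2)
        blocks = blocks.reshape(target.n_rows, target.n_cols, k * k)
        out = np.full(target.shape, src.nodata, dtype=src.values.dtype)
        for i in range(target.n_rows):
            for j in range(target.n_cols):
                votes = blocks[i, j]
                votes = votes[~src._nodata_mask(votes)]
                if votes.size == 0:
                    continue
                codes, counts = np.unique(votes, return_counts=True)
                out[i, j] = codes[np.argmax(counts)]  # unique() sorts: first max = lowest code
        return Raster(target, out, kind=src.kind, nodata=src.nodata, name=src.name)
    # upsampling: each fine cell inherits the containing coarse cell's code
    k = _ratio(src.geometry.cell_size, target.cell_size)
    need_r = -(-target.n_rows // k)
    need_c = -(-target.n_cols // k)
    if src.geometry.n_rows < need_r or src.geometry.n_cols < need_c:
        raise CoverageError("source does not cover the target extent")
    out = np.repeat(np.repeat(src.values, k, axis=0), k, axis=1)[: target.n_rows, : target.n_cols]
    return Raster(target, out, kind=src.kind, nodata=src.nodata, name=src.name)


def _keys_kernel(t: np.ndarray, a: float = -0.5) -> np.ndarray:
    """Keys cubic convolution kernel."""
    t = np.abs(t)
    out = np.zeros_like(t)
    m1 = t <= 1
    m2 = (t > 1) & (t < 2)
    out[m1] = (a + 2) * t[m1] ** 3 - (a + 3) * t[m1] ** 2 + 1
    out[m2] = a * t[m2] ** 3 - 5 * a * t[m2] ** 2 + 8 * a * t[m2] - 4 * a
    return out


def _cubic_weights(u: np.ndarray, n_src: int) -> tuple[np.ndarray, np.ndarray]:
    """4-tap Keys weights and (clamped) source indices for fractional positions u."""
    base = np.floor(u).astype(int)
    idx = base[:, None] + np.arange(-1, 3)[None, :]
    w = _keys_kernel(u[:, None] - idx)
    idx = np.clip(idx, 0, n_src - 1)
    return w, idx


def resample_continuous(src: Raster, target: GridGeometry) -> Raster:
    """Separable Keys cubic-convolution (a = -0.5) resampling.

    Interpolates source samples (located at source cell centers) at the
    target cell centers; edges clamp to the nearest valid sample.  Exact on
    constant and linear fields, which is the defining property asserted in
    the test suite.
    """
    if src.kind != CONTINUOUS:
        raise KindError("resample_continuous requires a continuous raster")
    sxs, sys = src.geometry.cell_centers()
    txs, tys = target.cell_centers()
    # fractional index of each target center in source sample space
    ux = (txs - sxs[0]) / src.geometry.cell_size
    uy = (sys[0] - tys) / src.geometry.cell_size
    wx, ix = _cubic_weights(ux, src.geometry.n_cols)
    wy, iy = _cubic_weights(uy, src.geometry.n_rows)
    vals = src.values.astype(float)
    # rows first: for each target row, combine 4 source rows
    inter = np.einsum("rk,rkc->rc", wy, vals[iy, :])
    out = np.einsum("ck,rck->rc", wx, inter[:, ix])
    return Raster(target, out, kind=CONTINUOUS, nodata=np.nan, name=src.name)


def allocate_proportional(src: Raster, target: GridGeometry) -> Raster:
    """Split each coarse cell's count equally among its k x k fine cells.

    Uniform-area proportional allocation: a coarse count c becomes c / k^2
    in every covered fine cell, so the global total is conserved exactly.
    """
    if src.kind != CONTINUOUS:
        raise KindError("allocate_proportional requires a continuous counts raster")
    vals = src.values.astype(float)
    if np.nanmin(vals) < 0:
        raise DomainError("allocate_proportional requires nonnegative values")
    k = _ratio(src.geometry.cell_size, target.cell_size)
    if src.geometry.origin != target.origin:
        raise CoverageError("source and target origins differ")
    need_r = -(-target.n_rows // k)
    need_c = -(-target.n_cols // k)
    if src.geometry.n_rows < need_r or src.geometry.n_cols < need_c:
        raise CoverageError("source does not cover the target extent")
    fine = np.kron(vals / (k * k), np.ones((k, k)))[: target.n_rows, : target.n_cols]
    return Raster(target, fine, kind=CONTINUOUS, nodata=np.nan, name=src.name)


def slope_aspect(elevation: Raster) -> tuple[Raster, Raster]:
    """Slope and aspect from elevation by Horn's eight-neighbor method.

    Slope is arctan of the gradient magnitude, in degrees.  Aspect is the
    compass direction of steepest *descent*, clockwise from north in
    [0, 360); flat cells get the sentinel ``FLAT_ASPECT`` (-1).  Border
    cells use edge replication.  Elevation is in meters; the cell size is
    converted from km.
    """
    if elevation.geometry.n_rows < 3 or elevation.geometry.n_cols < 3:
        raise SizeError("slope_aspect needs at least a 3x3 grid")
    z = np.pad(elevation.values.astype(float), 1, mode="edge")
    d = elevation.geometry.cell_size * 1000.0  # meters
    a, b, c = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    f, g_ = z[1:-1, :-2], z[1:-1, 2:]
    h, i_, j = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    dzdx = ((c + 2 * g_ + j) - (a + 2 * f + h)) / (8 * d)
    # rows increase southward; northward derivative uses top minus bottom
    dzdy = ((a + 2 * b + c) - (h + 2 * i_ + j)) / (8 * d)
    grad = np.hypot(dzdx, dzdy)
    slope = np.degrees(np.arctan(grad))
    aspect = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
    aspect[grad == 0] = FLAT_ASPECT
    geom = elevation.geometry
    return (
        Raster(geom, slope, kind=CONTINUOUS, name="slope"),
        Raster(geom, aspect, kind=CONTINUOUS, name="aspect"),
    )


def euclidean_distance(mask: Raster) -> Raster:
    """Center-to-center Euclidean distance (km) to the nearest 1-cell."""
    if mask.kind != BINARY:
        raise KindError("euclidean_distance requires a binary mask")
    m = mask.values == 1
    if not m.any():
        raise NoSourceError("mask contains no source cells")
    # distance_transform_edt measures to the nearest zero of its argument
    dist = ndimage.distance_transform_edt(~m) * mask.geometry.cell_size
    return Raster(mask.geometry, dist, kind=CONTINUOUS, name=f"dist_{mask.name or 'mask'}")


@dataclass
class IngestLog:
    """Row accounting for :func:`rasterize_fires`."""

    n_rows: int = 0
    n_malformed: int = 0
    n_below_confidence: int = 0
    n_outside_grid: int = 0
    n_used: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


#: Column names of the MCD14ML active-fire CSV dialect.
MCD14ML_COLUMNS = (
    "latitude",
    "longitude",
    "brightness",
    "scan",
    "track",
    "acq_date",
    "acq_time",
    "satellite",
    "confidence",
    "version",
)


def rasterize_fires(
    points: pd.DataFrame,
    geometry: GridGeometry,
    min_confidence: int = 95,
) -> tuple[Raster, IngestLog]:
    """Bin active-fire detections to a binary presence/absence raster.

    Detections with ``confidence < min_confidence`` are dropped (the
    default keeps only high-confidence detections, >= 95).  A cell is 1
    iff at least one surviving detection falls inside it.  Coordinates are
    taken from ``x_km``/``y_km`` when present (the synthetic dialect),
    otherwise ``longitude``/``latitude`` are interpreted as already
    projected grid km.  Malformed rows are rejected and counted, never
    aborted on.
    """
    log = IngestLog(n_rows=len(points))
    if {"x_km", "y_km"}.issubset(points.columns):
        xcol, ycol = "x_km", "y_km"
    else:
        xcol, ycol = "longitude", "latitude"
    def _col(name: str) -> pd.Series:
        if name in points.columns:
            return pd.to_numeric(points[name], errors="coerce")
        return pd.Series(np.nan, index=points.index, dtype=float)

    x = _col(xcol)
    y = _col(ycol)
    conf = _col("confidence")
    good = x.notna() & y.notna() & conf.notna() & (conf >= 0) & (conf <= 100)
    log.n_malformed = int((~good).sum())
    keep = good & (conf >= min_confidence)
    log.n_below_confidence = int((good & ~keep).sum())
    row, col, inside = geometry.locate(x[keep].to_numpy(), y[keep].to_numpy())
    log.n_outside_grid = int((~inside).sum())
    log.n_used = int(inside.sum())
    out = np.zeros(geometry.shape, dtype=np.uint8)
    out[row[inside], col[inside]] = 1
    return Raster(geometry, out, kind=BINARY, nodata=255, name="fire"), log


def fire_season_temperature(monthly: Sequence[Raster]) -> Raster:
    """Cellwise arithmetic mean of aligned monthly temperature rasters.

    Nodata (NaN) propagates: a cell missing any month is nodata.
    """
    if len(monthly) == 0:
        raise ValueError("at least one monthly raster is required")
    _require_aligned(*monthly)
    stack = np.stack([m.values.astype(float) for m in monthly])
    mean = stack.mean(axis=0)
    return Raster(monthly[0].geometry, mean, kind=CONTINUOUS, name="temperature")


@dataclass
class GridStack:
    """A set of mutually aligned rasters sharing one grid geometry."""

    geometry: GridGeometry
    covariates: dict[str, Raster] = field(default_factory=dict)
    protection: Raster | None = None
    fire: Raster | None = None

    def __post_init__(self) -> None:
        for r in self.rasters():
            if r.geometry != self.geometry:
                raise AlignmentError(f"raster {r.name!r} not aligned to stack geometry")

    def rasters(self) -> Iterable[Raster]:
        yield from self.covariates.values()
        if self.protection is not None:
            yield self.protection
        if self.fire is not None:
            yield self.fire

    def valid_mask(self) -> np.ndarray:
        """Complete-case mask: cells valid in every raster of the stack."""
        mask = np.ones(self.geometry.shape, dtype=bool)
        for r in self.rasters():
            mask &= r.valid
        return mask
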