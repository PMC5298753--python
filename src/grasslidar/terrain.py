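"""Ground surface model, height normalization and CHM rasterization.

The ground surface is a piecewise-linear interpolant over a Delaunay
triangulation of the ground-classified returns, evaluated barycentrically,
so it reproduces each ground return exactly at its own location.  Relative
(canopy) heights are the vertical distances of vegetation returns above this
surface, reported in centimetres.  The canopy height model grids those
relative heights *without interpolation*: each 0.2 m cell takes the maximum
relative height of the vegetation returns it contains, and cells with no
vegetation return carry the null marker -0.01, which all metric computations
exclude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from grasslidar.pointcloud import ClassLabel, PointCloud

CHM_NULL = -0.01
DEFAULT_CELL_SIZE = 0.2


class GroundSurfaceModel:
    """Piecewise-linear ground elevation queryable at any (x, y).

    Inside the convex hull of the ground returns the elevation is the
    barycentric interpolation on the Delaunay facet; outside it is the
    nearest ground return's elevation, flagged as extrapolated.
    """

    def __init__(self, x: np.ndarray, y: np.ndarray, z: np.ndarray):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        z = np.asarray(z, float)
        if x.size < 3:
            raise ValueError("need at least 3 ground returns")
        # collapse duplicate planimetric locations to their lowest return
        xy = np.column_stack([x, y])
        order = np.argsort(z)  # prefer lowest z among duplicates
        keep = np.zeros(x.size, bool)
        seen = {}
        for i in order:
            k = (round(x[i], 6), round(y[i], 6))
            if k not in seen:
                seen[k] = i
                keep[i] = True
        self.points = xy[keep]
        self.z = z[keep]
        if self.points.shape[0] < 3:
            raise ValueError("fewer than 3 distinct ground locations")
        try:
            self._tri = Delaunay(self.points)
        except Exception as exc:
            raise ValueError(f"degenerate ground geometry: {exc}") from exc
        if self._tri.simplices.size == 0:
            raise ValueError("degenerate (collinear) ground geometry")
        self._nn = cKDTree(self.points)

    def elevation(self, x, y, return_extrapolated: bool = False):
        """Ground elevation (m); optionally also the extrapolation mask."""
        x = np.atleast_1d(np.asarray(x, float))
        y = np.atleast_1d(np.asarray(y, float))
        q = np.column_stack([x, y])
        simplex = self._tri.find_simplex(q)
        inside = simplex >= 0
        out = np.empty(q.shape[0])
        if inside.any():
            s = simplex[inside]
            # barycentric coordinates from the stored affine transforms
            T = self._tri.transform[s]
            r = q[inside] - T[:, 2]
            bary2 = np.einsum("ijk,ik->ij", T[:, :2], r)
            bary = np.column_stack([bary2, 1 - bary2.sum(axis=1)])
            verts = self._tri.simplices[s]
            out[inside] = np.einsum("ij,ij->i", bary, self.z[verts])
        if (~inside).any():
            _, nn = self._nn.query(q[~inside])
            out[~inside] = self.z[nn]
        if return_extrapolated:
            return out, ~inside
        return out

    def __call__(self, x, y):
        return self.elevation(x, y)


def build_ground_model(cloud: PointCloud) -> GroundSurfaceModel:
    """Ground surface from the ground-classified returns of a cloud."""
    mask = cloud.classification == ClassLabel.GROUND
    if mask.sum() < 3:
        raise ValueError("fewer than 3 ground-classified returns")
    return GroundSurfaceModel(cloud.x[mask], cloud.y[mask], cloud.z[mask])


def normalize_heights(cloud: PointCloud, gsm: GroundSurfaceModel) -> PointCloud:
    """Attach relative heights (cm above the ground surface).

    Ground returns get exactly 0; vegetation/unclassified returns get
    z - gsm(x, y) in cm.  Returns outside the ground model's hull are
    flagged in ``outside_gsm`` and carry NaN so downstream metrics skip them.
    """
    out = cloud.copy()
    surf, extrapolated = gsm.elevation(cloud.x, cloud.y,
                                       return_extrapolated=True)
    rel = (cloud.z - surf) * 100.0
    rel[cloud.classification == ClassLabel.GROUND] = 0.0
    veg_outside = extrapolated & (cloud.classification != ClassLabel.GROUND)
    rel[veg_outside] = np.nan
    out.rel_height_cm = rel
    out.outside_gsm = veg_outside
    return out


@dataclass
class CanopyHeightModel:
    """0.2 m grid of maximum relative canopy height (cm).

    ``values[iy, ix]`` covers the half-open cell
    [origin + i*cell, origin + (i+1)*cell); the null marker -0.01 flags
    cells with no vegetation return and is excluded from every metric.
    ``counts`` stores the per-cell vegetation-return count.
    """

    origin: tuple[float, float]
    cell_size: float
    values: np.ndarray
    counts: np.ndarray = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid(self) -> np.ndarray:
        return self.values != CHM_NULL

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.values.shape
        xs = self.origin[0] + (np.arange(nx) + 0.5) * self.cell_size
        ys = self.origin[1] + (np.arange(ny) + 0.5) * self.cell_size
        return xs, ys

    def window_slice(self, xmin: float, ymin: float, xmax: float, ymax: float
                     ) -> np.ndarray:
        """Values of cells whose centres fall inside the window."""
        xs, ys = self.cell_centers()
        ix = np.flatnonzero((xs >= xmin) & (xs < xmax))
        iy = np.flatnonzero((ys >= ymin) & (ys < ymax))
        if ix.size == 0 or iy.size == 0:
            return np.empty((0, 0))
        return self.values[np.ix_(iy, ix)]


def rasterize_chm(cloud: PointCloud, cell_size: float = DEFAULT_CELL_SIZE,
                  origin: tuple[float, float] | None = None,
                  extent: tuple[float, float] | None = None
                  ) -> CanopyHeightModel:
    """Grid vegetation relative heights: per-cell max, no interpolation.

    ``origin`` defaults to the lower-left of the cloud bounding box (snap it
    explicitly to align with zone polygons).  Negative relative heights from
    ranging noise are clamped to 0 so occupied cells are always >= 0.
    """
    if cell_size <= 0:
        raise ValueError("cell size must be positive")
    if np.all(np.isnan(cloud.rel_height_cm)):
        raise ValueError("cloud is not normalized (no relative heights)")

    xmin, ymin, xmax, ymax = cloud.bounds()
    if origin is None:
        origin = (xmin, ymin)
    if extent is None:
        extent = (xmax - origin[0], ymax - origin[1])
    nx = max(1, int(np.ceil(extent[0] / cell_size)))
    ny = max(1, int(np.ceil(extent[1] / cell_size)))

    veg = (cloud.classification == ClassLabel.VEGETATION) \
        & np.isfinite(cloud.rel_height_cm)
    values = np.full((ny, nx), CHM_NULL)
    counts = np.zeros((ny, nx), dtype=np.int64)
    if veg.any():
        ix = np.floor((cloud.x[veg] - origin[0]) / cell_size).astype(np.int64)
        iy = np.floor((cloud.y[veg] - origin[1]) / cell_size).astype(np.int64)
        inb = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        ix, iy = ix[inb], iy[inb]
        rel = np.maximum(cloud.rel_height_cm[veg][inb], 0.0)
        flat = iy * nx + ix
        v = values.ravel()
        np.maximum.at(v, flat, rel)
        np.add.at(counts.ravel(), flat, 1)
    return CanopyHeightModel(origin=origin, cell_size=cell_size,
                             values=values, counts=counts)
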