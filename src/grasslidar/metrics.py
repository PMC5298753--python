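"""Canopy structure metrics over quadrat-sized windows.

Four indices are computed for an axis-aligned square window centred on a
quadrat: MeanCH and MaxCH (mean / maximum of the valid CHM cell heights,
cm), FVC (fraction of returns at or above the canopy threshold, default
2 cm) and sigma (population standard deviation of the canopy return
heights, cm).  Null CHM cells and NaN relative heights never enter a
computation; a window with nothing valid yields NaN rather than zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from grasslidar import grazing_tables as gt
from grasslidar.pointcloud import ClassLabel, PointCloud
from grasslidar.terrain import CHM_NULL, CanopyHeightModel


@dataclass(frozen=True)
class MetricWindow:
    """Square window of ``side`` m centred at (cx, cy)."""

    cx: float
    cy: float
    side: float = 1.0

    def __post_init__(self):
        if self.side <= 0:
            raise ValueError("window side must be positive")

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        h = self.side / 2.0
        return (self.cx - h, self.cy - h, self.cx + h, self.cy + h)


@dataclass
class CanopyMetrics:
    """Metric bundle for one window; NaN marks an undefined value."""

    mean_ch_cm: float
    max_ch_cm: float
    fvc: float
    sigma_cm: float
    n_valid: int
    flags: str = ""


def _window_cells(chm: CanopyHeightModel, w: MetricWindow) -> np.ndarray:
    cells = chm.window_slice(*w.bounds).ravel()
    return cells[cells != CHM_NULL]


def mean_ch(chm: CanopyHeightModel, w: MetricWindow) -> float:
    """Mean of valid CHM cell heights in the window (cm); NaN if none."""
    v = _window_cells(chm, w)
    return float(v.mean()) if v.size else float("nan")


def max_ch(chm: CanopyHeightModel, w: MetricWindow) -> float:
    """Maximum of valid CHM cell heights in the window (cm); NaN if none."""
    v = _window_cells(chm, w)
    return float(v.max()) if v.size else float("nan")


def _window_returns(cloud: PointCloud, w: MetricWindow) -> np.ndarray:
    xmin, ymin, xmax, ymax = w.bounds
    m = (cloud.x >= xmin) & (cloud.x < xmax) \
        & (cloud.y >= ymin) & (cloud.y < ymax)
    if cloud.outside_gsm is not None:
        m &= ~cloud.outside_gsm
    return m


def fvc(cloud: PointCloud, w: MetricWindow,
        threshold_cm: float = gt.CANOPY_RETURN_THRESHOLD_CM,
        basis: str = "returns", chm: CanopyHeightModel | None = None) -> float:
    """Fractional vegetation cover in the window.

    ``basis='returns'`` (default): canopy returns (relative height >=
    threshold) over all returns in the window — the return-ratio
    definition.  ``basis='cells'``: canopy CHM cells over valid CHM cells, a
    variant reading of the cell-based notation (requires ``chm``).
    """
    if basis == "cells":
        if chm is None:
            raise ValueError("cell-based FVC needs a CHM")
        v = _window_cells(chm, w)
        return float((v >= threshold_cm).mean()) if v.size else float("nan")
    if basis != "returns":
        raise ValueError(f"unknown FVC basis {basis!r}")
    m = _window_returns(cloud, w)
    if not m.any():
        return float("nan")
    rel = cloud.rel_height_cm[m]
    ok = np.isfinite(rel)
    if not ok.any():
        return float("nan")
    return float((rel[ok] >= threshold_cm).mean())


def height_sigma(cloud: PointCloud, w: MetricWindow,
                 threshold_cm: float = gt.CANOPY_RETURN_THRESHOLD_CM) -> float:
    """Population sd (divide by N) of canopy return heights in the window."""
    m = _window_returns(cloud, w)
    rel = cloud.rel_height_cm[m]
    canopy = rel[np.isfinite(rel) & (rel >= threshold_cm)]
    if canopy.size == 0:
        return float("nan")
    return float(np.sqrt(np.mean((canopy - canopy.mean()) ** 2)))


def extract_metrics_at_quadrats(chm: CanopyHeightModel, cloud: PointCloud,
                                centers, side: float = 1.0) -> "pandas.DataFrame":
    """One metrics row per quadrat centre; undefined rows are flagged.

    ``centers`` is an iterable of (x, y).  Centres outside the cloud extent
    produce a flagged (not silently dropped) row of NaNs.
    """
    import pandas as pd

    xmin, ymin, xmax, ymax = cloud.bounds()
    rows = []
    for cx, cy in centers:
        w = MetricWindow(cx, cy, side)
        flags = []
        if not (xmin <= cx <= xmax and ymin <= cy <= ymax):
            flags.append("outside_extent")
        mch = mean_ch(chm, w)
        xch = max_ch(chm, w)
        cov = fvc(cloud, w)
        sig = height_sigma(cloud, w)
        v = _window_cells(chm, w)
        if np.isnan(mch):
            flags.append("no_valid_cells")
        if np.isnan(cov):
            flags.append("no_returns")
        rows.append({
            "center_x": cx, "center_y": cy,
            "mean_ch_cm": mch, "max_ch_cm": xch, "fvc": cov,
            "sigma_cm": sig, "n_valid": int(v.size),
            "flags": ";".join(flags),
        })
    return pd.DataFrame(rows)
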