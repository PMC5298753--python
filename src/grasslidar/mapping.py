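"""Wall-to-wall prediction maps and stocking-rate evaluation.

Canopy metric rasters (1 m default) are computed with the same rules as the
quadrat metrics, calibrated models are applied cellwise, and the resulting
maps are summarized per grazing zone and per stocking rate to check that the
predictions track the six-level grazing gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from grasslidar import grazing_tables as gt
from grasslidar.metrics import MetricWindow, fvc as fvc_window, mean_ch as mean_ch_window
from grasslidar.pointcloud import PointCloud
from grasslidar.terrain import CHM_NULL, CanopyHeightModel


@dataclass
class PredictionRaster:
    """Gridded variable with NaN nodata and provenance metadata."""

    variable: str                  # e.g. 'biomass_g_m2', 'canopy_height_cm'
    origin: tuple[float, float]
    cell_size: float
    values: np.ndarray
    model_id: str = ""
    n_clamped: int = 0             # negative predictions clamped to 0

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.values.shape
        xs = self.origin[0] + (np.arange(nx) + 0.5) * self.cell_size
        ys = self.origin[1] + (np.arange(ny) + 0.5) * self.cell_size
        return xs, ys


@dataclass
class ZoneSummary:
    """Mean predicted value over one zone's valid pixels."""

    zone: str
    rate: int
    mean: float
    n_pixels: int
    flags: str = ""


def metric_rasters(chm: CanopyHeightModel, cloud: PointCloud,
                   resolution: float = 1.0,
                   extent: tuple[float, float] | None = None
                   ) -> dict[str, PredictionRaster]:
    """MeanCH and FVC rasters; each cell follows the quadrat-metric rules.

    Cells are anchored at the CHM origin.  A cell with no valid CHM cell gets
    NaN MeanCH; a cell with returns but no canopy return gets FVC 0; a cell
    with no returns at all gets NaN FVC.
    """
    origin = chm.origin
    if extent is None:
        ny_chm, nx_chm = chm.shape
        extent = (nx_chm * chm.cell_size, ny_chm * chm.cell_size)
    nx = max(1, int(np.ceil(extent[0] / resolution)))
    ny = max(1, int(np.ceil(extent[1] / resolution)))

    # MeanCH: group valid CHM cells by the coarse cell containing their centre
    xs, ys = chm.cell_centers()
    cgx, cgy = np.meshgrid(xs, ys)
    ix = np.floor((cgx.ravel() - origin[0]) / resolution).astype(np.int64)
    iy = np.floor((cgy.ravel() - origin[1]) / resolution).astype(np.int64)
    vals = chm.values.ravel()
    ok = (vals != CHM_NULL) & (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
    flat = iy[ok] * nx + ix[ok]
    sums = np.bincount(flat, weights=vals[ok], minlength=nx * ny)
    cnts = np.bincount(flat, minlength=nx * ny)
    mean_ch = np.full(nx * ny, np.nan)
    has = cnts > 0
    mean_ch[has] = sums[has] / cnts[has]

    # FVC: canopy returns / all returns per coarse cell
    rel = cloud.rel_height_cm
    fin = np.isfinite(rel)
    if cloud.outside_gsm is not None:
        fin &= ~cloud.outside_gsm
    jx = np.floor((cloud.x[fin] - origin[0]) / resolution).astype(np.int64)
    jy = np.floor((cloud.y[fin] - origin[1]) / resolution).astype(np.int64)
    inb = (jx >= 0) & (jx < nx) & (jy >= 0) & (jy < ny)
    flat_r = jy[inb] * nx + jx[inb]
    all_cnt = np.bincount(flat_r, minlength=nx * ny)
    canopy = rel[fin][inb] >= gt.CANOPY_RETURN_THRESHOLD_CM
    can_cnt = np.bincount(flat_r[canopy], minlength=nx * ny)
    fvc = np.full(nx * ny, np.nan)
    hasr = all_cnt > 0
    fvc[hasr] = can_cnt[hasr] / all_cnt[hasr]

    return {
        "mean_ch_cm": PredictionRaster("mean_ch_cm", origin, resolution,
                                       mean_ch.reshape(ny, nx)),
        "fvc": PredictionRaster("fvc", origin, resolution,
                                fvc.reshape(ny, nx)),
    }


def predict_map(metric: PredictionRaster, model, variable: str,
                clamp_max: float | None = None) -> PredictionRaster:
    """Apply a calibrated model cellwise; nodata in -> nodata out.

    Negative predictions are clamped to 0 and counted; ``clamp_max`` (e.g.
    100 for cover %) caps the upper end.
    """
    out = np.full_like(metric.values, np.nan, dtype=float)
    m = metric.valid
    out[m] = model.predict(metric.values[m])
    neg = m & (out < 0)
    out[neg] = 0.0
    if clamp_max is not None:
        out[m & (out > clamp_max)] = clamp_max
    return PredictionRaster(variable=variable, origin=metric.origin,
                            cell_size=metric.cell_size, values=out,
                            model_id=getattr(model, "family", ""),
                            n_clamped=int(neg.sum()))


def aggregate_zones(raster: PredictionRaster, zones) -> list[ZoneSummary]:
    """Per-zone mean over valid pixels (pixel centre-in-polygon test).

    ``zones`` is an iterable of objects with ``polygon``, ``rate`` and a
    ``name`` (ZoneSpec works).  Zones with zero valid pixels are flagged.
    """
    xs, ys = raster.cell_centers()
    gx, gy = np.meshgrid(xs, ys)
    flat_x, flat_y = gx.ravel(), gy.ravel()
    vals = raster.values.ravel()
    out = []
    for z in zones:
        inside = shapely.contains_xy(z.polygon, flat_x, flat_y)
        v = vals[inside]
        v = v[np.isfinite(v)]
        if v.size == 0:
            out.append(ZoneSummary(z.name, z.rate, float("nan"), 0,
                                   flags="no_valid_pixels"))
        else:
            out.append(ZoneSummary(z.name, z.rate, float(v.mean()), v.size))
    return out


def rate_level_means(summaries: list[ZoneSummary],
                     pooling: str = "replicate-mean") -> pd.DataFrame:
    """Pool the three replicate subplots of each stocking rate.

    ``replicate-mean`` averages the subplot means (equals pixel pooling when
    subplots are equal-area); ``pixel-pooled`` weights by pixel counts.  Both
    are reported by the CLI.
    """
    df = pd.DataFrame([{"zone": s.zone, "rate": s.rate, "mean": s.mean,
                        "n_pixels": s.n_pixels} for s in summaries])
    if pooling == "replicate-mean":
        g = df.groupby("rate")["mean"].mean()
    elif pooling == "pixel-pooled":
        df["w"] = df["mean"] * df["n_pixels"]
        g = df.groupby("rate").apply(
            lambda d: d["w"].sum() / d["n_pixels"].sum(),
            include_groups=False)
    else:
        raise ValueError(f"unknown pooling {pooling!r}")
    return g.rename("mean").reset_index()


def monotonicity_report(rate_values) -> dict:
    """Check a rate-ordered sequence for the expected decreasing gradient.

    Grazing removes canopy, so height / cover / biomass should be
    non-increasing from rate 0 to 5; real data violate this occasionally, so
    the report lists every adjacent increase rather than failing.
    """
    v = np.asarray(rate_values, dtype=float)
    violations = [int(i + 1) for i in range(v.size - 1) if v[i + 1] > v[i]]
    return {"non_increasing": len(violations) == 0,
            "violations_at_rate": violations,
            "values": v.tolist()}


def table_rate_aggregation(variable: int) -> np.ndarray:
    """Rate-level means recomputed from the published subplot means.

    ``variable``: 0 = height, 1 = cover, 2 = biomass.  This is the printed
    aggregation arithmetic (mean of the three equal-area replicates).
    """
    return gt.subplot_means(variable).mean(axis=1)
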