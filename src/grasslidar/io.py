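"""File formats and run configuration.

Point clouds travel as LAS 1.2 with a plain-CSV truth sidecar; rasters
(DEM / CHM / prediction maps) as ESRI ASCII grids; zones as GeoJSON;
quadrats, metrics and summaries as CSV; model registries as JSON; run
configuration as YAML.  Coordinates are planar projected metres (UTM-like);
the CRS is carried as a metadata string only, no reprojection happens.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping, shape

from grasslidar.pointcloud import PointCloud
from grasslidar.synthetic import ZoneSpec
from grasslidar.terrain import CHM_NULL, CanopyHeightModel

# deterministic child-seed offsets per stochastic stage
_SEED_OFFSETS = {"scene": 1, "flight": 2, "quadrats": 3, "split": 4,
                 "flightheight": 5}


def child_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    return (int(master_seed) * 1009 + _SEED_OFFSETS[stage]) % (2**31 - 1)


def write_truth_sidecar(cloud: PointCloud, path) -> None:
    """Truth labels and true relative heights as CSV next to a LAS file."""
    df = pd.DataFrame({
        "truth": cloud.truth if cloud.truth is not None else [],
        "intercepted": (cloud.intercepted.astype(int)
                        if cloud.intercepted is not None else []),
        "true_rel_h_cm": (cloud.true_rel_h_cm
                          if cloud.true_rel_h_cm is not None else []),
    })
    df.to_csv(path, index=False)


def read_truth_sidecar(cloud: PointCloud, path) -> PointCloud:
    df = pd.read_csv(path)
    if len(df) != len(cloud):
        raise ValueError("truth sidecar length does not match cloud")
    out = cloud.copy()
    out.truth = df["truth"].to_numpy(np.uint8)
    out.intercepted = df["intercepted"].to_numpy(bool)
    out.true_rel_h_cm = df["true_rel_h_cm"].to_numpy(float)
    return out


def write_ascii_grid(values: np.ndarray, origin: tuple[float, float],
                     cell_size: float, path, nodata: float = -9999.0) -> None:
    """ESRI ASCII grid; row 0 of ``values`` is the southernmost row."""
    v = np.array(values, dtype=float)
    v[~np.isfinite(v)] = nodata
    ny, nx = v.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {nx}\nnrows {ny}\n"
                 f"xllcorner {origin[0]:.6f}\nyllcorner {origin[1]:.6f}\n"
                 f"cellsize {cell_size:.6f}\nNODATA_value {nodata}\n")
        np.savetxt(fh, np.flipud(v), fmt="%.4f")


def read_ascii_grid(path) -> tuple[np.ndarray, tuple[float, float], float, float]:
    """Returns (values, origin, cell_size, nodata); nodata cells are NaN."""
    header = {}
    with open(path) as fh:
        for _ in range(6):
            k, val = fh.readline().split()
            header[k.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.flipud(np.atleast_2d(data))
    nodata = header.get("nodata_value", -9999.0)
    data[data == nodata] = np.nan
    return (data, (header["xllcorner"], header["yllcorner"]),
            header["cellsize"], nodata)


def write_chm(chm: CanopyHeightModel, path) -> None:
    write_ascii_grid(chm.values, chm.origin, chm.cell_size, path,
                     nodata=CHM_NULL)


def read_chm(path) -> CanopyHeightModel:
    values, origin, cell, _ = read_ascii_grid(path)
    values[~np.isfinite(values)] = CHM_NULL
    return CanopyHeightModel(origin=origin, cell_size=cell, values=values)


def write_zones(zones, path) -> None:
    features = []
    for z in zones:
        features.append({
            "type": "Feature",
            "geometry": mapping(z.polygon),
            "properties": {"rate": z.rate, "replicate": z.replicate,
                           "mean_height_cm": z.mean_height_cm,
                           "cover": z.cover, "biomass": z.biomass},
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_zones(path) -> list[ZoneSpec]:
    with open(path) as fh:
        fc = json.load(fh)
    zones = []
    for f in fc["features"]:
        p = f["properties"]
        zones.append(ZoneSpec(polygon=shape(f["geometry"]), rate=p["rate"],
                              replicate=p.get("replicate", "W"),
                              mean_height_cm=p.get("mean_height_cm", 15.0),
                              cover=p.get("cover", 0.7),
                              biomass=p.get("biomass")))
    return zones


DEFAULT_CONFIG = {
    "crs": "EPSG:32650",       # metadata only
    "master_seed": 0,
    "scene": {"subplot_side": 20.0, "clump_density": 3.0, "slope_deg": 1.5},
    "flight": {"height": 40.0, "noise_sd_cm": 2.0, "density_at_40m": 26.0},
    "filter": {"seed_cell": 2.0, "max_terrain_angle": 6.0, "iter_angle": 8.0,
               "iter_dist": 0.05, "max_iterations": 8, "refine": True,
               "refine_cell": 2.0, "veg_threshold_cm": 3.0},
    "chm": {"cell_size": 0.2},
    "metrics": {"window_side": 1.0, "canopy_threshold_cm": 2.0},
    "calibration": {"n_train": 66},
    "mapping": {"resolution": 1.0},
    "flightheight": {"n_seeds": 5},
    "quadrats": {"per_zone": 5, "gps_jitter": False},
}


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in DEFAULT_CONFIG.items()}
    for k, v in user.items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:12]
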