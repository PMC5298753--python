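"""High-level pipeline stages tying the modules into the survey workflow.

Each function is one workflow box: simulate -> classify -> normalize/CHM ->
quadrat metrics -> calibrate -> map -> zonal evaluation.  The CLI wraps
these; tests and the acceptance script call them directly.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd

from grasslidar import calibration as cal
from grasslidar import grazing_tables as gt
from grasslidar.ground_filter import FilterParams, classify_ground, classification_accuracy
from grasslidar.io import child_seed
from grasslidar.mapping import (PredictionRaster, aggregate_zones,
                                metric_rasters, monotonicity_report,
                                predict_map, rate_level_means)
from grasslidar.metrics import extract_metrics_at_quadrats
from grasslidar.pointcloud import ClassLabel, PointCloud
from grasslidar.synthetic import (FlightConfig, Scene, default_scene_spec,
                                  generate_scene, sample_quadrats,
                                  simulate_flight)
from grasslidar.terrain import (CanopyHeightModel, build_ground_model,
                                normalize_heights, rasterize_chm)


def simulate_survey(master_seed: int = 0, subplot_side: float = 20.0,
                    clump_density: float = 3.0, slope_deg: float = 1.5,
                    flight_height: float = 40.0, per_zone: int = 5,
                    gps_jitter: bool = False,
                    flight_overrides: dict | None = None):
    """Scene + 40 m survey + field quadrats, all seeded from one master."""
    spec = default_scene_spec(subplot_side=subplot_side,
                              clump_density=clump_density,
                              seed=child_seed(master_seed, "scene"))
    spec = replace(spec, slope_deg=slope_deg)
    scene = generate_scene(spec)
    fc = FlightConfig(height=flight_height,
                      seed=child_seed(master_seed, "flight"),
                      **(flight_overrides or {}))
    cloud = simulate_flight(scene, fc)
    quadrats = sample_quadrats(scene, per_zone=per_zone,
                               seed=child_seed(master_seed, "quadrats"),
                               gps_jitter=gps_jitter)
    return scene, cloud, quadrats


def classify_and_normalize(cloud: PointCloud,
                           params: FilterParams = FilterParams(),
                           chm_origin=None, chm_extent=None,
                           cell_size: float = 0.2):
    """Filter, build the ground model, normalize and rasterize the CHM."""
    labeled = classify_ground(cloud, params)
    gsm = build_ground_model(labeled)
    norm = normalize_heights(labeled, gsm)
    chm = rasterize_chm(norm, cell_size=cell_size, origin=chm_origin,
                        extent=chm_extent)
    accuracy = None
    if cloud.has_truth:
        accuracy = classification_accuracy(labeled, cloud)
    return norm, gsm, chm, accuracy


def quadrat_table(chm: CanopyHeightModel, norm: PointCloud,
                  quadrats: pd.DataFrame, side: float = 1.0) -> pd.DataFrame:
    """Lidar metrics at the recorded quadrat centres, merged with field data."""
    centers = quadrats[["x", "y"]].to_numpy()
    lidar = extract_metrics_at_quadrats(chm, norm, centers, side=side)
    merged = pd.concat([quadrats.reset_index(drop=True),
                        lidar.drop(columns=["center_x", "center_y"])], axis=1)
    merged["fvc_pct"] = 100.0 * merged["fvc"]
    return merged


def calibrate_suite(table: pd.DataFrame, n_train: int = 66, seed: int = 0
                    ) -> dict:
    """Fit the study's model families for each response on one shared split.

    Responses: field mean height ~ lidar MeanCH; field cover ~ lidar FVC;
    biomass ~ {MeanCH (4 families), MaxCH linear, FVC exponential,
    MeanCH + FVC multiple}.  Returns per-response candidate lists, the
    best-by-test-RMSE model, and the leaderboard.
    """
    usable = table.dropna(subset=["mean_ch_cm", "fvc"])
    if len(usable) < n_train + 2:
        raise ValueError(f"only {len(usable)} usable quadrats for a "
                         f"{n_train}-sample training split")
    train, test = cal.train_test_split(usable, n_train=n_train, seed=seed)

    def run(response, x_col, families, x2_col=None):
        models = []
        y_max = float(usable[response].max())
        for fam in families:
            try:
                if fam == "multiple-linear":
                    m = cal.fit_multiple(train[x_col], train[x2_col],
                                         train[response])
                    cal.score_on_test(m, test[x_col], test[response], y_max,
                                      x2_test=test[x2_col])
                    m.predictors = (x_col, x2_col)
                else:
                    tr = train
                    # nonlinear families are fitted on their domain subset
                    if fam in ("logarithmic", "power"):
                        tr = tr[tr[x_col] > 0]
                    if fam in ("power", "exponential"):
                        tr = tr[tr[response] > 0]
                    if len(tr) < len(train):
                        warnings.warn(
                            f"{response} ~ {x_col} [{fam}]: fitted on "
                            f"{len(tr)}/{len(train)} in-domain training rows")
                    m = cal.fit_model(tr[x_col], tr[response], fam)
                    cal.score_on_test(m, test[x_col], test[response], y_max)
                    m.predictors = (x_col,)
                m.response = response
                models.append(m)
            except (ValueError, RuntimeError) as exc:
                warnings.warn(f"{response} ~ {x_col} [{fam}] skipped: {exc}")
        return models

    single_families = ("linear", "logarithmic", "power", "exponential")
    out = {}
    out["height"] = run("field_mean_h_cm", "mean_ch_cm", single_families)
    out["cover"] = run("field_cover_pct", "fvc_pct", ("linear",))
    biomass = run("field_biomass", "mean_ch_cm", single_families)
    biomass += run("field_biomass", "max_ch_cm", ("linear",))
    biomass += run("field_biomass", "fvc_pct", ("exponential",))
    biomass += run("field_biomass", "mean_ch_cm", ("multiple-linear",),
                   x2_col="fvc_pct")
    out["biomass"] = biomass

    best, boards = {}, []
    for resp, models in out.items():
        if models:
            b, board = cal.select_best(models)
            best[resp] = b
            board.insert(0, "response_key", resp)
            boards.append(board)
    # the biomass map uses the best *single* regression
    singles = [m for m in out["biomass"] if m.family != "multiple-linear"]
    best["biomass_single"] = cal.select_best(singles)[0] if singles else None
    return {"models": out, "best": best,
            "leaderboard": pd.concat(boards, ignore_index=True),
            "split_seed": seed}


def build_maps(chm: CanopyHeightModel, norm: PointCloud, suite: dict,
               resolution: float = 1.0,
               extent: tuple[float, float] | None = None) -> dict:
    """1 m metric rasters + calibrated height / cover / biomass maps."""
    rasters = metric_rasters(chm, norm, resolution=resolution, extent=extent)
    fvc_pct = rasters["fvc"].values * 100.0
    fvc_pct_raster = PredictionRaster("fvc_pct", rasters["fvc"].origin,
                                      resolution, fvc_pct)
    best = suite["best"]
    maps = dict(rasters)
    if "height" in best:
        maps["pred_height_cm"] = predict_map(rasters["mean_ch_cm"],
                                             best["height"],
                                             "canopy_height_cm")
    if "cover" in best:
        maps["pred_cover_pct"] = predict_map(fvc_pct_raster, best["cover"],
                                             "fractional_cover_pct",
                                             clamp_max=100.0)
    if best.get("biomass_single") is not None:
        mdl = best["biomass_single"]
        src = rasters["mean_ch_cm"] if mdl.predictors[0] == "mean_ch_cm" \
            else fvc_pct_raster
        maps["pred_biomass"] = predict_map(src, mdl, "biomass_g_m2")
    return maps


def evaluate_zones(maps: dict, zones, scene: Scene | None = None) -> dict:
    """Zone / rate-level summaries and gradient-monotonicity reports."""
    out = {"zones": {}, "rates": {}, "monotonicity": {}}
    for key in ("pred_height_cm", "pred_cover_pct", "pred_biomass"):
        if key not in maps:
            continue
        summaries = aggregate_zones(maps[key], zones)
        out["zones"][key] = summaries
        rates = rate_level_means(summaries)
        out["rates"][key] = rates
        out["monotonicity"][key] = monotonicity_report(
            rates.sort_values("rate")["mean"].to_numpy())
    if scene is not None:
        out["truth_rates"] = (
            pd.DataFrame(scene.zone_truth)
            .groupby("rate")[["mean_height_cm", "cover", "biomass"]].mean())
    return out
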