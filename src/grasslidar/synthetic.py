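"""Synthetic grassland scenes and a discrete-return lidar flight simulator.

The generator builds a meadow-steppe plot with known truth: a gently sloping
ground surface (< 3 deg, matching the study terrain), a Boolean model of
circular plant clumps whose cover and height are calibrated per grazing zone,
and a linear height->biomass link fitted to the six published rate-level
summaries.  The flight simulator lays pulses on a uniform grid whose areal
density scales inversely with altitude, intersects each pulse footprint with
the clump discs, and draws a canopy echo height as (max clump top within the
footprint) x B with B ~ Beta(1, 2) — a penetration factor whose mean of 1/3
matches the observed ratio of lidar to field canopy heights.  All echoes get
Gaussian ranging noise; dual returns are emitted only when canopy and ground
echoes separate by more than 1 m, so grassland clouds are effectively
single-return.

Truth labels follow the canopy-return definition used throughout the
analysis: an echo is vegetation truth when its true (pre-noise) relative
height is at or above the 2 cm canopy threshold; echoes scattered from the
lowest centimetres of the canopy are ground truth but keep
``intercepted=True`` so footprint-interception properties remain testable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import Polygon, box

from grasslidar import grazing_tables as gt
from grasslidar.pointcloud import ClassLabel, PointCloud

# generator constants (documented in docs/methods.md)
HEIGHT_LOGNORMAL_SIGMA = 0.4       # within-zone spread of clump top heights
RADIUS_LOGNORMAL_SIGMA = 0.15      # spread of clump radii
TERRAIN_UNDULATION_AMP_M = 0.05    # smooth microtopography amplitude
TERRAIN_WAVELENGTHS_M = (27.0, 41.0)
BIOMASS_NOISE_SD = 40.0            # g/m^2, quadrat-level scatter around the link
FIELD_HEIGHT_NOISE_SD_CM = 0.5
FIELD_COVER_NOISE_SD_PCT = 2.0
GPS_JITTER_RMSE_M = 2.61           # horizontal RMSE of the handheld GPS


@dataclass(frozen=True)
class ZoneSpec:
    """One grazing subplot: polygon, stocking-rate id and canopy targets."""

    polygon: Polygon
    rate: int                      # stocking rate 0-5
    replicate: str = "W"           # W / M / E
    mean_height_cm: float = 15.0
    cover: float = 0.7             # fraction in [0, 1]
    biomass: float | None = None   # g/m^2; None -> from the height link

    @property
    def name(self) -> str:
        return f"{self.replicate}{self.rate}"


@dataclass(frozen=True)
class SceneSpec:
    """Scene recipe: extent, terrain, zone layout and clump density."""

    extent: tuple[float, float] = (120.0, 60.0)
    slope_deg: float = 1.5
    zones: tuple[ZoneSpec, ...] = ()
    clump_density: float = 3.0     # clumps / m^2
    seed: int = 0

    def __post_init__(self):
        if self.extent[0] <= 0 or self.extent[1] <= 0:
            raise ValueError("extent must be positive")
        if not 0 <= self.slope_deg <= 3:
            raise ValueError("terrain slope must be within [0, 3] degrees")
        if self.clump_density < 0:
            raise ValueError("clump density must be non-negative")
        for z in self.zones:
            if not 0 <= z.cover < 1:
                raise ValueError(
                    f"zone {z.name}: cover target {z.cover} outside [0, 1)")


def default_scene_spec(subplot_side: float = 20.0, clump_density: float = 3.0,
                       seed: int = 0) -> SceneSpec:
    """The default study layout at desk scale.

    Three replicate rows (W/M/E) by six stocking-rate columns of square
    subplots, targets set to the published rate-level summaries.
    """
    zones = []
    for j, rep in enumerate(gt.REPLICATES):
        for i, rate in enumerate(gt.RATES):
            poly = box(i * subplot_side, j * subplot_side,
                       (i + 1) * subplot_side, (j + 1) * subplot_side)
            zones.append(ZoneSpec(
                polygon=poly, rate=rate, replicate=rep,
                mean_height_cm=float(gt.MEAN_HEIGHT_RATE_PRINTED[i]),
                cover=float(gt.COVER_RATE_PRINTED[i]) / 100.0,
            ))
    return SceneSpec(extent=(6 * subplot_side, 3 * subplot_side),
                     zones=tuple(zones), clump_density=clump_density, seed=seed)


def single_zone_spec(mean_height_cm: float, cover: float,
                     extent: tuple[float, float] = (20.0, 20.0),
                     rate: int = 0, clump_density: float = 3.0,
                     seed: int = 0) -> SceneSpec:
    """One square zone filling the whole extent (unit-test workhorse)."""
    zone = ZoneSpec(polygon=box(0, 0, *extent), rate=rate,
                    mean_height_cm=mean_height_cm, cover=cover)
    return SceneSpec(extent=extent, zones=(zone,), clump_density=clump_density,
                     seed=seed)


@dataclass
class _Terrain:
    slope: float                   # dz/dx, dimensionless
    amp: float
    wavelengths: tuple[float, float]
    phases: tuple[float, float]
    z0: float = 670.0              # base elevation, m

    def elevation(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        lx, ly = self.wavelengths
        px, py = self.phases
        return (self.z0 + self.slope * x
                + self.amp * np.sin(2 * np.pi * x / lx + px)
                + self.amp * np.sin(2 * np.pi * y / ly + py))


@dataclass
class Scene:
    """Realized grassland scene with recomputable truth.

    Plant clumps are discs: centre (m), radius (m) and top height (cm).
    Truth for any window is obtained by fine sub-sampling of the Boolean
    model; per-zone truth is cached at generation time.
    """

    spec: SceneSpec
    terrain: _Terrain
    cx: np.ndarray
    cy: np.ndarray
    radius: np.ndarray
    top_cm: np.ndarray
    zone_index: np.ndarray
    zone_truth: list[dict] = field(default_factory=list)

    @property
    def n_elements(self) -> int:
        return self.cx.size

    def ground_elevation(self, x, y):
        return self.terrain.elevation(x, y)

    def canopy_top_at(self, x, y, inflate: float = 0.0) -> np.ndarray:
        """Max clump top height (cm) covering each query point; 0 if bare.

        ``inflate`` enlarges every disc radius (used for footprint
        intersection: a pulse intercepts a clump when their discs overlap).
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        top = np.zeros(x.size)
        if self.n_elements == 0 or x.size == 0:
            return top
        tree = cKDTree(np.column_stack([x, y]))
        hits = tree.query_ball_point(
            np.column_stack([self.cx, self.cy]), self.radius + inflate)
        for i, idx in enumerate(hits):
            if idx:
                idx = np.asarray(idx)
                np.maximum.at(top, idx, self.top_cm[i])
        return top

    def truth_window(self, bounds: tuple[float, float, float, float],
                     step: float = 0.05) -> dict:
        """True cover / heights / expected biomass for a window.

        ``bounds`` = (xmin, ymin, xmax, ymax).  Computed by sub-sampling the
        Boolean clump model on a ``step``-spaced grid; biomass is the
        noiseless height->biomass link (the expected quadrat biomass).
        """
        xmin, ymin, xmax, ymax = bounds
        xs = np.arange(xmin + step / 2, xmax, step)
        ys = np.arange(ymin + step / 2, ymax, step)
        gx, gy = np.meshgrid(xs, ys)
        top = self.canopy_top_at(gx.ravel(), gy.ravel())
        covered = top > 0
        cover = float(covered.mean()) if top.size else 0.0
        if covered.any():
            mean_h = float(top[covered].mean())
            max_h = float(top[covered].max())
            min_h = float(top[covered].min())
        else:
            mean_h = max_h = min_h = float("nan")
        slope, intercept = gt.biomass_height_link()
        biomass = max(0.0, slope * mean_h + intercept) if covered.any() else 0.0
        return {"cover": cover, "mean_height_cm": mean_h,
                "max_height_cm": max_h, "min_height_cm": min_h,
                "biomass": biomass}


def _calibrate_zone(rng, zone: ZoneSpec, density: float,
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Place clumps in one zone and calibrate radii/heights to the targets."""
    area = zone.polygon.area
    n = int(round(density * area))
    if n == 0 or zone.cover == 0:
        if zone.cover > 0 and n == 0:
            warnings.warn(f"zone {zone.name}: zero clump density with a "
                          f"positive cover target; zone left bare")
        return (np.empty(0),) * 4

    # Boolean-model radius for the cover target at this density
    base_r = np.sqrt(-np.log1p(-zone.cover) / (density * np.pi))
    if not np.isfinite(base_r):
        raise ValueError(f"zone {zone.name}: cover target {zone.cover} "
                         f"infeasible at density {density}")

    xmin, ymin, xmax, ymax = zone.polygon.bounds
    # rejection-sample centres inside the polygon
    centres = np.empty((0, 2))
    while centres.shape[0] < n:
        cand = rng.uniform([xmin, ymin], [xmax, ymax], size=(2 * n, 2))
        keep = shapely.contains_xy(zone.polygon, cand[:, 0], cand[:, 1])
        centres = np.vstack([centres, cand[keep]])
    centres = centres[:n]

    s = RADIUS_LOGNORMAL_SIGMA
    radii = base_r * rng.lognormal(-s * s, s, size=n)   # E[r^2] = base_r^2
    hs = HEIGHT_LOGNORMAL_SIGMA
    tops = zone.mean_height_cm * rng.lognormal(-hs * hs / 2, hs, size=n)
    return centres[:, 0], centres[:, 1], radii, tops


def generate_scene(spec: SceneSpec) -> Scene:
    """Build a scene whose per-zone realized truth is within 10 % of targets.

    After placement, each zone's cover is corrected once via the Boolean-model
    area relation and its heights are rescaled linearly so that the
    sub-sampled true mean height matches the target (rescaling commutes with
    the per-point max, so this is exact up to sampling error).
    """
    rng = np.random.default_rng(spec.seed)
    slope = np.tan(np.radians(spec.slope_deg))
    terrain = _Terrain(slope=slope, amp=TERRAIN_UNDULATION_AMP_M,
                       wavelengths=TERRAIN_WAVELENGTHS_M,
                       phases=tuple(rng.uniform(0, 2 * np.pi, 2)))

    parts = {k: [] for k in ("cx", "cy", "r", "top", "zi")}
    for zi, zone in enumerate(spec.zones):
        cx, cy, r, top = _calibrate_zone(rng, zone, spec.clump_density)
        parts["cx"].append(cx)
        parts["cy"].append(cy)
        parts["r"].append(r)
        parts["top"].append(top)
        parts["zi"].append(np.full(cx.size, zi, dtype=int))

    scene = Scene(
        spec=spec, terrain=terrain,
        cx=np.concatenate(parts["cx"]) if parts["cx"] else np.empty(0),
        cy=np.concatenate(parts["cy"]) if parts["cy"] else np.empty(0),
        radius=np.concatenate(parts["r"]) if parts["r"] else np.empty(0),
        top_cm=np.concatenate(parts["top"]) if parts["top"] else np.empty(0),
        zone_index=np.concatenate(parts["zi"]) if parts["zi"] else np.empty(0, int),
    )

    # per-zone correction passes against sub-sampled truth
    slope_b, intercept_b = gt.biomass_height_link()
    for zi, zone in enumerate(spec.zones):
        sel = scene.zone_index == zi
        if sel.any() and zone.cover > 0:
            truth = scene.truth_window(zone.polygon.bounds, step=0.1)
            # one Boolean-model radius correction for cover
            if 0 < truth["cover"] < 1 and zone.cover > 0:
                factor = np.sqrt(np.log1p(-zone.cover) /
                                 np.log1p(-truth["cover"]))
                scene.radius[sel] *= factor
                truth = scene.truth_window(zone.polygon.bounds, step=0.1)
            # exact linear height rescale
            if np.isfinite(truth["mean_height_cm"]) and truth["mean_height_cm"] > 0:
                scene.top_cm[sel] *= zone.mean_height_cm / truth["mean_height_cm"]
            truth = scene.truth_window(zone.polygon.bounds, step=0.1)
        else:
            truth = {"cover": 0.0, "mean_height_cm": float("nan"),
                     "max_height_cm": float("nan"),
                     "min_height_cm": float("nan"), "biomass": 0.0}
        truth["zone"] = zone.name
        truth["rate"] = zone.rate
        truth["replicate"] = zone.replicate
        if truth["cover"] > 0:
            truth["biomass"] = (zone.biomass if zone.biomass is not None else
                                max(0.0, slope_b * truth["mean_height_cm"]
                                    + intercept_b))
        scene.zone_truth.append(truth)
    return scene


def footprint_diameter(divergence_mrad: float, range_m: float) -> float:
    """Laser footprint diameter (m) under the small-angle approximation."""
    if divergence_mrad < 0 or range_m < 0:
        raise ValueError("divergence and range must be non-negative")
    return divergence_mrad * 1e-3 * range_m


@dataclass(frozen=True)
class FlightConfig:
    """UAV survey parameters (defaults = the published flight setup)."""

    height: float = 40.0                   # m
    speed: float = gt.FLIGHT_SPEED_MS      # m/s
    rotation_rate: float = gt.ROTATION_RATE_HZ
    scan_angle: tuple[float, float] = gt.SCAN_ANGLE_DEG
    divergence_mrad: float = gt.BEAM_DIVERGENCE_MRAD
    noise_sd_cm: float = gt.RANGING_NOISE_SD_CM
    density_at_40m: float = gt.POINT_DENSITY_AT_40M
    dual_return_sep_m: float = gt.DUAL_RETURN_SEPARATION_M
    seed: int = 0

    def __post_init__(self):
        lo, hi = gt.FLIGHT_HEIGHT_RANGE_M
        if not lo <= self.height <= hi:
            raise ValueError(
                f"flight height {self.height} m outside the surveyed "
                f"range [{lo:.0f}, {hi:.0f}] m")

    @property
    def density(self) -> float:
        """Pulse density at this altitude: a fixed pulse rate spread over a
        swath that widens linearly with height, so density ~ 1/h."""
        return self.density_at_40m * 40.0 / self.height

    @property
    def footprint(self) -> float:
        return footprint_diameter(self.divergence_mrad, self.height)


def simulate_flight(scene: Scene, flight: FlightConfig) -> PointCloud:
    """Simulate a survey: one echo per pulse (dual only past the 1 m split).

    Pulses sit on a jittered uniform grid at ``flight.density``; a pulse whose
    footprint disc overlaps at least one clump returns a canopy echo at
    (max clump top within the footprint) x Beta(1, 2), otherwise a ground
    echo; every echo is perturbed by Gaussian ranging noise.
    """
    rng = np.random.default_rng(flight.seed)
    ex, ey = scene.spec.extent
    d = 1.0 / np.sqrt(flight.density)
    nx = max(1, int(np.ceil(ex / d)))
    ny = max(1, int(np.ceil(ey / d)))
    gx, gy = np.meshgrid((np.arange(nx) + 0.5) * d, (np.arange(ny) + 0.5) * d)
    px = gx.ravel() + rng.uniform(-d / 2, d / 2, gx.size)
    py = gy.ravel() + rng.uniform(-d / 2, d / 2, gy.size)
    inside = (px >= 0) & (px <= ex) & (py >= 0) & (py <= ey)
    px, py = px[inside], py[inside]
    n = px.size

    r_fp = flight.footprint / 2.0
    top = scene.canopy_top_at(px, py, inflate=r_fp)
    intercepted = top > 0

    true_rel_cm = np.zeros(n)
    k = int(intercepted.sum())
    if k:
        true_rel_cm[intercepted] = top[intercepted] * rng.beta(1.0, 2.0, k)

    ground_z = scene.ground_elevation(px, py)
    noise = rng.normal(0.0, flight.noise_sd_cm / 100.0, n)
    z = ground_z + true_rel_cm / 100.0 + noise

    truth = np.where(true_rel_cm >= gt.CANOPY_RETURN_THRESHOLD_CM,
                     ClassLabel.VEGETATION, ClassLabel.GROUND).astype(np.uint8)

    # dual-return mode: also record the ground echo when separated by > 1 m
    dual = intercepted & (true_rel_cm / 100.0 > flight.dual_return_sep_m)
    if dual.any():
        m = int(dual.sum())
        gz = (scene.ground_elevation(px[dual], py[dual])
              + rng.normal(0.0, flight.noise_sd_cm / 100.0, m))
        px = np.concatenate([px, px[dual]])
        py = np.concatenate([py, py[dual]])
        z = np.concatenate([z, gz])
        true_rel_cm = np.concatenate([true_rel_cm, np.zeros(m)])
        truth = np.concatenate(
            [truth, np.full(m, ClassLabel.GROUND, dtype=np.uint8)])
        intercepted = np.concatenate([intercepted, np.zeros(m, bool)])
        rnum = np.concatenate([np.ones(n, np.uint8), np.full(m, 2, np.uint8)])
    else:
        rnum = np.ones(n, dtype=np.uint8)

    return PointCloud(x=px, y=py, z=z, return_number=rnum,
                      truth=truth, intercepted=intercepted,
                      true_rel_h_cm=true_rel_cm)


def sample_quadrats(scene: Scene, per_zone: int = 5, seed: int = 0,
                    side: float = 1.0, gps_jitter: bool = False) -> "pandas.DataFrame":
    """Draw field quadrats with truth-derived 'field' measurements.

    Each zone receives ``per_zone`` 1 x 1 m quadrats at random interior
    positions (>= 2 m apart at desk scale).  Field values are window truth
    plus measurement noise; biomass adds the quadrat-level scatter around the
    height link.  ``gps_jitter`` applies the handheld-GPS co-location error
    (horizontal RMSE 2.61 m) to the *recorded* centre coordinates.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    slope_b, intercept_b = gt.biomass_height_link()
    rows = []
    qid = 0
    for zi, zone in enumerate(scene.spec.zones):
        xmin, ymin, xmax, ymax = zone.polygon.bounds
        margin = side / 2 + 0.5
        placed = []
        attempts = 0
        while len(placed) < per_zone and attempts < 1000:
            attempts += 1
            cand = rng.uniform([xmin + margin, ymin + margin],
                               [xmax - margin, ymax - margin])
            if all(np.hypot(cand[0] - p[0], cand[1] - p[1]) >= 2.0
                   for p in placed):
                placed.append(cand)
        for cx, cy in placed:
            w = (cx - side / 2, cy - side / 2, cx + side / 2, cy + side / 2)
            t = scene.truth_window(w)
            mean_h = t["mean_height_cm"] if np.isfinite(t["mean_height_cm"]) else 0.0
            rec_x, rec_y = cx, cy
            if gps_jitter:
                sd = GPS_JITTER_RMSE_M / np.sqrt(2.0)
                rec_x += rng.normal(0, sd)
                rec_y += rng.normal(0, sd)
            rows.append({
                "id": qid, "x": rec_x, "y": rec_y,
                "true_x": cx, "true_y": cy,
                "zone": zone.name, "rate": zone.rate,
                "field_mean_h_cm": max(0.0, mean_h + rng.normal(0, FIELD_HEIGHT_NOISE_SD_CM)),
                "field_max_h_cm": max(0.0, (t["max_height_cm"] if np.isfinite(t["max_height_cm"]) else 0.0)
                                      + rng.normal(0, FIELD_HEIGHT_NOISE_SD_CM)),
                "field_min_h_cm": max(0.0, (t["min_height_cm"] if np.isfinite(t["min_height_cm"]) else 0.0)
                                      + rng.normal(0, FIELD_HEIGHT_NOISE_SD_CM)),
                "field_cover_pct": float(np.clip(
                    100 * t["cover"] + rng.normal(0, FIELD_COVER_NOISE_SD_PCT), 0, 100)),
                "field_biomass": max(0.0, slope_b * mean_h + intercept_b
                                     + rng.normal(0, BIOMASS_NOISE_SD)),
            })
            qid += 1
    return pd.DataFrame(rows)
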