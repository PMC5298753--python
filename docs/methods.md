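# Methods

This note documents the models behind `grasslidar`: what the synthetic
scenes and the flight simulator emulate, how the processing chain is
defined, the defaults that matter, and what the package's passing tests do
and do not demonstrate about real surveys.

## Study system

The target system is a meadow-steppe cattle-grazing experiment: one plot
holding three replicates (W/M/E) of six stocking rates (0, 2, 3, 4, 6, 8
head per subplot), grazed annually since 2009. Field quadrats summarize
each subplot by mean canopy height (cm), fractional cover (%) and clipped
dry biomass (g·m⁻²); at the rate level these span roughly 6–33.7 cm,
62–77 % and 56–391 g·m⁻². Terrain slope is below 3°. The scanner is a
rotating multi-beam 903 nm unit flown at 40 m (survey) and 10–120 m
(sensitivity experiment): 3 mrad beam divergence (0.12 m footprint at
40 m), ±2 cm ranging accuracy, ~26 pulses·m⁻² at 40 m, dual-return mode
that only splits echoes separated by more than 1 m — over grass the clouds
are effectively single-return.

## Synthetic scenes

A scene is a Boolean model of circular plant clumps on a gently sloping
plane (default 1.5°, plus two ~5 cm sinusoidal undulations of ~30–40 m
wavelength as microtopography):

- **Clump density** defaults to 3 clumps·m⁻² — patch-forming steppe
  grasses (*Leymus*, *Stipa*) form decimetre clumps; the density together
  with the per-zone cover target fixes the base clump radius through the
  Boolean-model relation `cover = 1 − exp(−λπr²)` (radii get ±15 %
  lognormal jitter with E[r²] preserved).
- **Clump top heights** are lognormal (σ_log = 0.4, ≈ 40 % CV — a
  realistic within-sward spread) scaled per zone.
- **Calibration.** After placement each zone gets one Boolean-model radius
  correction toward its cover target and one exact linear rescale of its
  heights toward its mean-height target (rescaling commutes with the
  pointwise max); realized truth is then within a few percent of targets,
  well inside the 10 % contract, and is recomputable by sub-sampling.
- **Biomass link.** True biomass density is `10.82 · meanheight_cm + 22.0`
  g·m⁻², a least-squares fit through the six rate-level (height, biomass)
  pairs of the grazing experiment; zone truth uses the link exactly, while
  each simulated field quadrat adds N(0, 40²) g·m⁻² of clipping/plot
  scatter. Field height and cover measurements add N(0, 0.5 cm) and
  N(0, 2 %) noise. Optionally, recorded quadrat centres get a 2-D Gaussian
  co-location error with horizontal RMSE 2.61 m (the handheld-GPS error;
  off by default).

## Flight simulation

Pulses sit on a jittered square grid with areal density
`26 · (40 / h)` pts·m⁻² — a fixed pulse rate spread over a swath widening
linearly with altitude. Scan geometry is simplified to uniform spacing;
the retained ±5° scan window enters only through the density and footprint
models, because per-channel geometry is not recoverable for this scene
scale. Each pulse has footprint diameter `divergence × range`
(small-angle). A pulse whose footprint disc overlaps ≥ 1 clump disc
returns a canopy echo at relative height `max(clump tops in footprint) × B`
with `B ~ Beta(1, 2)`: a penetration factor with mean 1/3, matching the
observed ratio of lidar-derived to field-measured mean canopy heights in
this kind of sward. Non-intercepted pulses return a ground echo. All
echoes get N(0, 2 cm) ranging noise (the sensor's ±2 cm accuracy read as
one sd). Dual returns are emitted only past the 1 m separation threshold.

**Truth labels.** An echo is truth-labeled *vegetation* when its true
(pre-noise) relative height is at or above the 2 cm canopy threshold —
the same convention the metrics use to define a canopy return; an echo
scattered from the lowest 2 cm of the sward is physically
indistinguishable from soil at the sensor's own ranging accuracy. The raw
geometric fact "this pulse's footprint intersected a plant" is kept
separately as `intercepted` for footprint-interception properties.

## Ground filtering

Progressive densification: (1) per-seed-cell (2 m) minima become seeds,
pruned against a plane fit at the 6° maximum terrain angle; (2) a
piecewise-linear surface over the ground set accepts returns within the
iteration distance (5 cm) and angle (8°) thresholds, rebuilt until a fixed
point; (3) a refinement surface — per-2 m-cell mean of the densified
ground returns, re-meaned after an asymmetric one-sd trim (vegetation
contaminates the ground class only from above), nearest-filled and
bilinearly interpolated — reclassifies every return: ground below 3 cm
relative height, vegetation above, `other` for isolated returns or returns
more than 3 residual-sd below the surface.

The published workflow's filter is proprietary and its parameters
unreported; only its quality-control bar (> 90 % correctly classified) is
known. Defaults here were therefore chosen against that bar on simulated
scenes. Two caveats matter:

- An iteration distance of 10 cm (a common default for taller vegetation)
  exceeds the entire canopy of the shortest zones; 5 cm plus the 3 cm
  refinement threshold suits centimetre-scale swards.
- With 2 cm ranging noise and Beta(1,2) penetration, the true relative
  height of a canopy echo in a 6 cm sward has mean ≈ 2 cm — the same
  order as the noise. The per-return accuracy of *any* classifier on such
  scenes is bounded near 0.79–0.91 depending on canopy level (measured
  with a perfect surface and per-scene optimal threshold); the filter
  lands within ~0.01–0.03 of that bound. The > 90 % bar is attainable in
  this simulation only for the tallest canopy level, so pipeline accuracy
  reports of ~0.76–0.82 across all levels indicate noise-limited
  performance, not a filtering defect.

## Normalization, CHM, metrics

The ground surface model is a Delaunay-triangulated piecewise-linear
interpolant through the ground-classified returns (exact at each return;
nearest-neighbour extrapolation outside the hull is flagged). Relative
heights are `z − surface` in cm; ground returns are exactly 0. The CHM
grids vegetation returns at 0.2 m with the per-cell maximum and no
interpolation; cells without vegetation returns hold the null marker
−0.01 and are excluded from every metric. Cell membership is half-open
([k·0.2, (k+1)·0.2), lower-indexed cell wins at boundaries); the grid
origin snaps to the cloud bounding box unless given.

MeanCH/MaxCH come from valid CHM cells whose centres fall in the window;
FVC is by default the return ratio (canopy returns ≥ 2 cm over all
returns; the threshold is configurable, comparison is ≥), with a
cell-based variant behind a flag; σ is the population sd (÷N) of canopy
return heights. Windows with nothing valid yield NaN, never 0.

## Calibration and mapping

One shared random 66/24 train/test split feeds every family. R² is
computed on the training sample on the original scale for all families
(the transformed-scale alternative is not used); power and exponential
fits run Levenberg–Marquardt from log-linearized starts (tolerance 1e-10,
max 10⁴ evaluations) and are fitted on their domain subset (x > 0, y > 0)
when clipped zero-biomass quadrats occur. RMSE is test-sample; rRMSE
divides by the maximum of the full observed response. Model selection
ranks by test RMSE, ties by higher R², then fewer parameters; p-values
come from the regression F statistic. Prediction maps apply the winning
models cellwise at 1 m; negative predictions are clamped to 0 and counted,
cover is capped at 100 %. Rate-level summaries are reported both as the
mean of the three replicate subplot means and pixel-pooled (identical for
equal-area subplots).

## Flight-height experiment

A 50 × 20 m single-zone scene at the rate-3 canopy (13.7 cm, 69.7 %
cover) is surveyed at 10–120 m in 10 m steps, five seeded flights per
altitude, each run through the full filter/normalize chain; area-wide
point-based MeanCH, σ and FVC (no CHM — the statistics are defined over
the whole survey polygon) are averaged over replicates. Two structural
consequences of the echo model are worth knowing when comparing with real
surveys:

- σ *rises* mildly with altitude here (≈ 3.8 → 4.1 cm): the echo height is
  `max(tops in footprint) × B`, and a larger footprint raises the expected
  maximum, hence the dispersion. Real waveforms average over the
  footprint, which is what makes dispersion fall with altitude in field
  data; the max-based model deliberately omits within-footprint averaging.
- Measured FVC is roughly flat-to-falling with altitude even though the
  true canopy-return fraction rises (≈ 0.51 → 0.68): the ground surface is
  interpolated through ground-classified returns, and the share of
  sub-canopy (< 2 cm) echoes in that class grows with the interception
  fraction, lifting the estimated surface by ~1 cm at 120 m and pushing
  marginal returns below the 2 cm threshold. This bias afflicts any
  per-return classifier under these conditions, halved but not removed by
  the trimmed refinement surface.

## Problem sizes and determinism

Default sizes are desk-scale by design: 20 m subplots (120 × 60 m plot),
20 × 20 m filter-benchmark scenes, 50 × 20 m altitude-sweep scene — the
spatial statistics of interest (per-window metrics, per-zone means) are
stationary in subplot size, and quadrat counts (90; 5 per subplot,
≥ 2 m apart) match the field design. Every stochastic stage draws from a
child seed derived deterministically from one master seed; identical
configuration yields byte-identical outputs. Scene truth is recomputable
by sub-sampling at any resolution (tests verify < 1 % drift at half-step).

## What passing tests do not show

The simulator has homogeneous zones (constant clump density and height
distribution within a subplot), circular clumps, no intensity or waveform
information, no multi-return vegetation, and no trajectory/georeferencing
error beyond the optional quadrat GPS jitter. Consequently quadrat-scale
FVC variation within a zone is almost entirely sampling noise, which
attenuates quadrat-level correlations between lidar metrics (real swards
show within-site structure that couples cover and height much more
strongly). Regression R² values on synthetic data (~0.75 for biomass) are
tighter than typical field results because the biomass link is linear by
construction; they validate the arithmetic, not field-accuracy claims.
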