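# grasslidar

Canopy structure and aboveground biomass of grasslands from UAV
discrete-return lidar.

Low-altitude drone lidar can measure grass canopy height, fractional
vegetation cover (FVC) and — through regression calibration against clipped
quadrats — dry aboveground biomass, over whole paddocks instead of a handful
of sample frames. `grasslidar` implements that workflow as a tested Python
package for a meadow-steppe grazing experiment: eighteen subplots, three
replicates of six stocking rates (0–8 head of cattle), with mean canopy
heights spanning ~6–34 cm. Because the original survey data are not public,
the package ships a first-class synthetic-data module that generates
grassland scenes with known truth and simulates the scanner (903 nm
rotating multi-beam unit, 3 mrad beam divergence, 26 pts·m⁻² at 40 m,
±2 cm ranging accuracy), so every stage is testable end to end.

## The method

1. **Ground filtering.** Returns are classified ground / vegetation / other
   by slope-and-angle progressive densification: per-cell minima seed a
   triangulated provisional surface; returns within the angle and distance
   thresholds are accepted iteratively; a gridded trimmed-mean refinement
   surface then reclassifies every return by its relative height.
2. **Normalization and CHM.** A piecewise-linear ground surface model
   interpolates the ground returns exactly; vegetation returns get relative
   heights *h* (cm) above it. The canopy height model (CHM) grids these
   *without interpolation*: each 0.2 m cell takes the maximum relative
   height, empty cells carry the null marker −0.01 and are excluded from
   all statistics.
3. **Canopy metrics** over a 1 × 1 m window *W* centred on a quadrat
   (i, j):

   - MeanCH(i,j) = Mean[h(u,v)], (u,v) ∈ W — mean of valid CHM cells,
   - MaxCH(i,j) = Max[h(u,v)], (u,v) ∈ W,
   - FVC(i,j) = N_{h≥2 cm} / N_all — ratio of canopy returns (≥ 2 cm) to
     all returns in W,
   - σ = √(Σ[h − h̄]² / N) — population sd of canopy return heights.

4. **Calibration.** Linear, logarithmic, power and exponential regressions
   of field measurements on lidar metrics, trained on a random 66-sample
   split and scored on the held-out 24 by RMSE = √(Σ(yᵢ − ŷᵢ)²/N) and
   rRMSE = 100 · RMSE / max(y); plus two-predictor multiple linear models.
5. **Mapping and evaluation.** The best models produce 1 m canopy height,
   cover and biomass maps; zone means per subplot and stocking rate are
   checked against the expected grazing gradient (values should fall as
   stocking rate rises).
6. **Flight-height sensitivity.** A fixed 50 × 20 m scene is surveyed at
   10–120 m altitude in 10 m steps (pulse density ∝ 1/h, footprint =
   divergence × range), tabulating MeanCH, σ and FVC per altitude.

## Worked example

```bash
grasslidar all --seed 0 --out runs/demo --skip-flightheight
```

simulates the default 18-subplot scene (120 × 60 m at desk scale), flies
the 40 m survey (~187 000 returns), filters, builds the CHM, extracts
metrics at 90 quadrats, calibrates, maps and evaluates, printing:

```
filter accuracy 0.821; best biomass model power on mean_ch_cm: RMSE 53.7 g/m2 (10.2%) -> runs/demo
```

Read: 82.1 % of returns were classified into the truth class; the best
single-predictor biomass model (here a power law on the lidar mean canopy
height) predicts the held-out quadrats with an RMSE of 53.7 g·m⁻², i.e.
10.2 % of the maximum observed biomass. `runs/demo/leaderboard.csv` ranks
every fitted family per response; e.g. the linear biomass model on MeanCH
scores R² = 0.748, RMSE = 53.8 g·m⁻², and adding FVC as a second predictor
moves the test RMSE by only ~1 g·m⁻² — canopy height does almost all the
work. `zone_summaries.csv` and `monotonicity.json` report the per-zone and
per-stocking-rate means and any violations of the grazing gradient.

The altitude sweep (`grasslidar flightheight --out trends.csv`) reports,
per flight height, the area-wide mean canopy height, σ and FVC averaged
over five seeded replicate flights.

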