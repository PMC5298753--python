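"""Reference characteristics of the six-level cattle-grazing experiment.

A 1 km^2 meadow-steppe plot holds 18 subplots: three replicates (W/M/E,
west/middle/east) of six stocking rates (0, 2, 3, 4, 6 and 8 head of young
cattle, coded 0-5).  Field quadrats give each subplot a mean canopy height
(cm), fractional cover (%) and dry aboveground biomass (g m^-2).  These
summaries drive the synthetic scene generator: per-zone canopy targets
default to the rate-level values below.

The ``*_RATE_PRINTED`` arrays are the rate-level summaries as published;
note that they were compiled from the quadrat data directly (with two
quadrats excluded), so two entries differ slightly from the arithmetic
mean of the three replicate subplot means.
"""

from __future__ import annotations

import numpy as np

RATES = (0, 1, 2, 3, 4, 5)
REPLICATES = ("W", "M", "E")

# subplot-level summaries: {(replicate, rate): (mean height cm, cover %, biomass g/m^2)}
SUBPLOT = {
    ("W", 0): (38.0, 78.6, 528.2),
    ("M", 0): (30.4, 74.0, 180.0),
    ("E", 0): (32.7, 76.8, 465.3),
    ("E", 1): (27.3, 81.0, 195.7),
    ("M", 1): (20.5, 73.0, 299.2),
    ("W", 1): (16.0, 71.0, 140.5),
    ("E", 2): (13.6, 72.0, 134.0),
    ("M", 2): (10.6, 81.0, 150.5),
    ("W", 2): (12.5, 78.0, 149.7),
    ("E", 3): (13.5, 68.0, 180.6),
    ("M", 3): (16.4, 70.0, 225.1),
    ("W", 3): (11.3, 71.0, 312.0),
    ("E", 4): (5.2, 69.0, 121.1),
    ("M", 4): (4.9, 58.0, 83.2),
    ("W", 4): (10.2, 64.0, 101.5),
    ("E", 5): (8.2, 57.6, 59.7),
    ("M", 5): (4.9, 57.6, 28.6),
    ("W", 5): (4.9, 72.0, 82.7),
}

# rate-level summaries as printed (heights cm, cover %, biomass g/m^2)
MEAN_HEIGHT_RATE_PRINTED = np.array([33.7, 21.2, 12.2, 13.7, 6.8, 6.0])
COVER_RATE_PRINTED = np.array([76.5, 75.0, 77.0, 69.7, 63.7, 62.4])
BIOMASS_RATE_PRINTED = np.array([391.2, 211.8, 144.7, 239.2, 101.9, 56.0])

# sensor / flight parameters of the rotating multi-beam scanner
FLIGHT_SPEED_MS = 5.0
ROTATION_RATE_HZ = 5.0
SCAN_ANGLE_DEG = (-5.0, 5.0)          # retained channels
BEAM_DIVERGENCE_MRAD = 3.0
WAVELENGTH_NM = 903.0
POINT_DENSITY_AT_40M = 26.0           # pts / m^2
RANGING_NOISE_SD_CM = 2.0             # sensor ranging accuracy read as one sd
DUAL_RETURN_SEPARATION_M = 1.0
FLIGHT_HEIGHT_RANGE_M = (10.0, 120.0)

# best published single-predictor biomass model: biomass = a * MeanCH_lidar + b
BIOMASS_MODEL_SLOPE = 34.785
BIOMASS_MODEL_INTERCEPT = 7.081
BIOMASS_MAX_OBSERVED = 582.5          # g/m^2, rRMSE denominator

CANOPY_RETURN_THRESHOLD_CM = 2.0      # returns at >= 2 cm count as canopy


def subplot_means(variable: int) -> np.ndarray:
    """(6, 3) array of subplot-level values; rows = rates, cols = W/M/E.

    ``variable``: 0 = mean height (cm), 1 = cover (%), 2 = biomass (g/m^2).
    """
    out = np.empty((6, 3))
    for i, rate in enumerate(RATES):
        for j, rep in enumerate(REPLICATES):
            out[i, j] = SUBPLOT[(rep, rate)][variable]
    return out


def biomass_height_link() -> tuple[float, float]:
    """OLS fit of rate-level biomass on rate-level mean height.

    Returns (slope g m^-2 cm^-1, intercept g m^-2).  This linear link is the
    generator's ground-truth biomass model (the field relationship is only
    published as a scatter plot, so the six rate-level pairs are used).
    """
    h = MEAN_HEIGHT_RATE_PRINTED
    b = BIOMASS_RATE_PRINTED
    slope, intercept = np.polyfit(h, b, 1)
    return float(slope), float(intercept)
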