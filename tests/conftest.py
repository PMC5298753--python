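"""Shared fixtures: small synthetic scenes and one full-survey pipeline run.

Everything is generated at test time from fixed seeds; nothing is read from
disk.  The session-scoped ``survey`` fixture runs the complete default
pipeline once (18 zones, 40 m flight, 90 quadrats) and is shared by the
calibration / mapping / acceptance tests.
"""

import numpy as np
import pytest

from grasslidar import pipeline as pl
from grasslidar.synthetic import (FlightConfig, generate_scene,
                                  simulate_flight, single_zone_spec)


@pytest.fixture(scope="session")
def tall_scene():
    """20 x 20 m single-zone scene at the ungrazed canopy level."""
    return generate_scene(single_zone_spec(33.7, 0.765, extent=(20.0, 20.0),
                                           seed=11))


@pytest.fixture(scope="session")
def tall_cloud(tall_scene):
    return simulate_flight(tall_scene, FlightConfig(seed=21))


@pytest.fixture(scope="session")
def survey():
    """Full default pipeline at master seed 0 (the package defaults)."""
    scene, cloud, quadrats = pl.simulate_survey(master_seed=0)
    norm, gsm, chm, accuracy = pl.classify_and_normalize(
        cloud, chm_origin=(0.0, 0.0), chm_extent=scene.spec.extent)
    table = pl.quadrat_table(chm, norm, quadrats)
    return {"scene": scene, "cloud": cloud, "quadrats": quadrats,
            "norm": norm, "gsm": gsm, "chm": chm, "accuracy": accuracy,
            "table": table}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
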