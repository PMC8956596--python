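import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from urbexbio.raster_core import GridSpec
from urbexbio.synthetic_data import SynthConfig, generate_world


@pytest.fixture(scope="session")
def small_world():
    """A 60x60 synthetic world shared by accounting/pipeline tests."""
    cfg = SynthConfig(
        seed=7,
        spec=GridSpec(60, 60, 1000.0),
        scenarios=("SSP1", "SSP5"),
        n_ecoregions=6,
        n_biomes=3,
        n_countries=4,
        n_protected_areas=6,
    )
    return generate_world(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
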