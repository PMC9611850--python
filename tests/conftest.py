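import numpy as np
import pytest

from agrifuse import (
    SimConfig,
    match_footprints,
    ndvi,
    render_satellite,
    render_uav,
    simulate_scene,
)
from agrifuse.simulate import vigour_for_canopy_ndvi


@pytest.fixture(scope="session")
def noisy_scene():
    """Small vineyard scene with realistic acquisition noise."""
    return simulate_scene(
        SimConfig(field_width_m=30, field_height_m=20, noise_sd=0.01, seed=1)
    )


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free scene with canopy NDVI pinned at 0.8 and soil at 0.15."""
    return simulate_scene(
        SimConfig(
            field_width_m=30,
            field_height_m=20,
            vigour_base=vigour_for_canopy_ndvi(0.8),
            noise_sd=0.0,
            seed=0,
        )
    )


@pytest.fixture(scope="session")
def clean_uav(clean_scene):
    return render_uav(clean_scene, 0.05)


@pytest.fixture(scope="session")
def clean_sat(clean_scene):
    return render_satellite(clean_scene, 10.0)


@pytest.fixture(scope="session")
def clean_corr(clean_sat, clean_uav):
    return match_footprints(clean_sat.grid, clean_uav.grid)


@pytest.fixture(scope="session")
def clean_uav_ndvi(clean_uav):
    return ndvi(clean_uav)
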