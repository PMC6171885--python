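import numpy as np
import pytest

import fmc_hazard as fh
from fmc_hazard.synthetic import FireParams


@pytest.fixture(scope="session")
def small_config():
    return fh.SimulationConfig(rows=48, cols=48, years=(2008,), seed=11)


@pytest.fixture(scope="session")
def scene(small_config):
    """One fully generated 48x48 scene shared by read-only tests."""
    landcover = fh.generate_landcover(small_config)
    latent = fh.generate_fmc(small_config, landcover, 2008)
    indices = fh.fmc_to_indices(latent, landcover)
    reflectance = fh.indices_to_reflectance(indices)
    return {"config": small_config, "landcover": landcover, "latent": latent,
            "indices": indices, "reflectance": reflectance}


@pytest.fixture(scope="session")
def fire_rich_scene():
    """A scene with enough fires for the statistical analyses."""
    cfg = fh.SimulationConfig(
        rows=60, cols=60, years=(2008,), seed=5,
        fire_params=FireParams(expected_per_year=220))
    landcover = fh.generate_landcover(cfg)
    latent = fh.generate_fmc(cfg, landcover, 2008)
    fires = fh.generate_fires(latent, landcover, cfg)
    return {"config": cfg, "landcover": landcover, "latent": latent,
            "fires": fires, "stacks": {2008: latent}}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
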