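import numpy as np
import pytest
import xarray as xr

from lakech4.pipeline import PipelineParams, run_pipeline
from lakech4.synthetic import (
    generate_world,
    noise_free_config,
    small_world_config,
)


@pytest.fixture(scope="session")
def small_world():
    """A reduced synthetic world with the default (noisy) study conditions."""
    return generate_world(small_world_config(seed=2))


@pytest.fixture(scope="session")
def small_result(small_world):
    return run_pipeline(small_world, PipelineParams())


@pytest.fixture(scope="session")
def noise_free_world():
    """Analytically solvable world: no scatter, no temperature dependence."""
    cfg = noise_free_config(seed=3, n_sites=120, n_records=400, lon_max=3.0)
    return generate_world(cfg)


@pytest.fixture(scope="session")
def noise_free_result(noise_free_world):
    return run_pipeline(noise_free_world, PipelineParams())


def make_layers(perma, ice, soc, temp):
    """Single-cell geophysical layer stack from scalar values."""
    from lakech4.constants import PERMAFROST_CODES

    def grid(v):
        return (("lat", "lon"), np.array([[float(v)]]))

    return xr.Dataset(
        {
            "permafrost_category": (("lat", "lon"),
                                    np.array([[PERMAFROST_CODES[perma]]], dtype=np.int8)),
            "ground_ice": grid(ice),
            "soc": grid(soc),
            "annual_soil_temp": grid(temp),
        },
        coords={"lat": [60.125], "lon": [0.125]},
    )
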