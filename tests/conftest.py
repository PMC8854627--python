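import numpy as np
import pytest

from cortexmesh import SimulationParams, simulate_pair


@pytest.fixture(scope="session")
def default_pair():
    """One full-scale simulated meshwork pair, shared across tests."""
    return simulate_pair(SimulationParams(rng_seed=42))


@pytest.fixture(scope="session")
def small_params():
    """Cheap simulation parameters: 2 um field on a 10 nm raster."""
    return SimulationParams(
        n_seed_filaments=8,
        field_size_um=(2.0, 2.0),
        raster_pixel_nm=10.0,
        bin_factor=4,
        rng_seed=3,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
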