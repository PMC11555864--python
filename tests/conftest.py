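import numpy as np
import pytest

from rhizospec.cube_io import Datacube, Wavelengths
from rhizospec.synthgen import SceneParams, make_scene


@pytest.fixture(scope="session")
def default_scene():
    """One scene at the default noise conditions, shared across tests."""
    return make_scene(SceneParams(seed=7))


@pytest.fixture(scope="session")
def noiseless_scene():
    return make_scene(
        SceneParams(seed=7, sigma_additive=0.0, sigma_multiplicative=0.0)
    )


@pytest.fixture
def small_cube():
    """Deterministic random 12 x 10 x 8 reflectance cube."""
    rng = np.random.default_rng(42)
    data = rng.uniform(0.05, 0.9, size=(12, 10, 8))
    return Datacube(data, Wavelengths(np.linspace(470, 900, 8)))


def constant_cube(value: float, shape=(6, 6, 5)) -> Datacube:
    return Datacube(
        np.full(shape, value, dtype=float),
        Wavelengths(np.linspace(470, 900, shape[2])),
    )
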