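import numpy as np
import pytest

from cropsar.synthetic import (
    default_reflectance_profile,
    default_scattering_profile,
    generate_landcover,
    sample_polygons,
)


@pytest.fixture(scope="session")
def small_map():
    """64x64 landscape with 3 fields per class."""
    return generate_landcover((64, 64), fields_per_class=3, seed=7)


@pytest.fixture(scope="session")
def small_polygons(small_map):
    return sample_polygons(small_map, seed=7)


@pytest.fixture(scope="session")
def sar_profile():
    return default_scattering_profile()


@pytest.fixture(scope="session")
def optical_profile():
    return default_reflectance_profile()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def uniform_map(code: int, shape=(44, 44)):
    """Single-class scene for recovery experiments."""
    from cropsar.synthetic import LandCoverMap

    return LandCoverMap(
        labels=np.full(shape, code, dtype=np.int16), polygons=[]
    )
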