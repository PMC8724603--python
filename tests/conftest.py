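import numpy as np
import pytest

from glycoims import (
    ChemistryConfig, EnumerationBounds, IMSDataset, Spectrum, build_database,
)


@pytest.fixture(scope="session")
def native_db():
    """Default-bounds native-chemistry database (session-cached)."""
    return build_database()


@pytest.fixture(scope="session")
def small_db():
    """A small, quickly enumerated database for matching tests."""
    bounds = EnumerationBounds(
        hex=(3, 7), hexnac=(2, 6), dhex=(0, 2), neuac=(0, 2), sulfate=(0, 1)
    )
    return build_database(bounds, ChemistryConfig(mass_range_lo=490, mass_range_hi=3000))


@pytest.fixture
def grid3x3():
    """A 3x3 dataset with one centroid per pixel and known intensities."""
    pixels = []
    for y in range(3):
        for x in range(3):
            pixels.append((x, y, Spectrum([1000.0 + x, 2000.0 + y], [1.0 + x, 2.0 + y])))
    return IMSDataset(pixels=pixels, grid_shape=(3, 3), mz_range=(900.0, 2100.0))
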