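import numpy as np
import pytest

from pbi.geometry import FrequencyGrid, ImagingGeometry, MaterialOptics, MATERIALS


@pytest.fixture
def rng():
    return np.random.default_rng(20221102)


@pytest.fixture
def unit_grid():
    """Small even grid with unit pixel size (Nyquist at pi)."""
    return FrequencyGrid(shape=(8, 8), pixel_size=1.0)


@pytest.fixture
def water():
    return MATERIALS["water"]


@pytest.fixture
def pmma():
    return MATERIALS["pmma"]


@pytest.fixture
def unit_material():
    """delta*Delta/mu = 10 at Delta = 1 m, for W = 1 m grids."""
    return MaterialOptics.from_delta_mu(delta=10.0, mu=1.0, energy_keV=24.0)


@pytest.fixture
def geometry_unit():
    return ImagingGeometry(pixel_size=1.0, distance=1.0, shape=(8, 8))
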