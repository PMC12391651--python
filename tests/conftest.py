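import numpy as np
import pytest

from tchasim.imaging import ImagingConfig
from tchasim.kinetics import OccupancyParams
from tchasim.surface import SurfaceLayer
from tchasim.tether import FPLDesign
from tchasim.transport import FlowCellAssay, diffusivity_dsdna


@pytest.fixture(scope="session")
def design5():
    """5-segment tether with the 15 nm rods of the headline configuration."""
    return FPLDesign(5, rod_length_nm=15.0)


@pytest.fixture(scope="session")
def design9():
    """9-segment tether with 15 nm rods."""
    return FPLDesign(9, rod_length_nm=15.0)


@pytest.fixture(scope="session")
def layer():
    """Measured neutravidin monolayer on a 100x100 um footprint."""
    return SurfaceLayer()


@pytest.fixture(scope="session")
def assay(design9):
    """Reference flow-cell assay: 1000x50 um channel, 10 uL/min, 30 min,
    tether-construct diffusivity from the dsDNA power law."""
    return FlowCellAssay(diffusivity_m2_s=diffusivity_dsdna(design9.total_bp))


@pytest.fixture(scope="session")
def imaging_config():
    return ImagingConfig()


@pytest.fixture(scope="session")
def occupancy():
    return OccupancyParams()


@pytest.fixture
def rng():
    return np.random.default_rng(0)
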