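import numpy as np
import pytest

from ulm3d import array_design as ad
from ulm3d.beamform import AcousticMedium


@pytest.fixture(scope="session")
def medium():
    return AcousticMedium()


@pytest.fixture(scope="session")
def layout():
    """The default pair of 256-element spiral apertures (deterministic)."""
    return ad.design_apertures()


@pytest.fixture(scope="session")
def full_matrix_positions():
    """All 1024 available elements of the 32 x 35 gridded probe."""
    table = ad.MatrixGrid().element_table()
    return table[table["available"]][["x_m", "y_m"]].to_numpy()
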