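import numpy as np
import pytest

from vortexhab import BedProfile, CrossSectionGrid, build_section_geometry

UNIT_FLAT = BedProfile("flat", width=1.0, max_depth=1.0)


@pytest.fixture
def unit_grid():
    """10x10 fully wet unit square grid with zero velocity."""
    return build_section_geometry(UNIT_FLAT, 10, 10, 1.0)


def solid_body_grid(n: int = 20, omega: float = 1.0) -> CrossSectionGrid:
    """Fully wet unit grid in solid-body rotation with curl ``omega``."""
    g = build_section_geometry(UNIT_FLAT, n, n, 1.0)
    yy, zz = g.meshgrid()
    g.v_y = -0.5 * omega * (zz - 0.5)
    g.v_z = 0.5 * omega * (yy - 0.5)
    return g


def masked_grid(wet: np.ndarray) -> CrossSectionGrid:
    """Unit-square grid with an arbitrary wet mask and zero velocity."""
    nz, ny = wet.shape
    g = build_section_geometry(UNIT_FLAT, ny, nz, 1.0)
    g.wet = wet.astype(bool)
    return g
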