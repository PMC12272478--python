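import numpy as np
import pytest

from drmap.phantoms import field_grid, sphere_contours, tube_contours


@pytest.fixture(scope="session")
def sphere50():
    """Sphere of radius 50 mm centred at the origin, pole-dense slicing."""
    return sphere_contours(50.0)


@pytest.fixture(scope="session")
def uniform_grid():
    """Spatially uniform 42 Gy field on a 2 mm grid."""
    return field_grid(lambda z, y, x: np.full_like(z, 42.0), spacing=(2, 2, 2))


@pytest.fixture(scope="session")
def radial_grid():
    """Radial field f(r) = 10 + 0.5 r Gy on a fine grid."""
    return field_grid(lambda z, y, x: 10.0 + 0.5 * np.sqrt(z**2 + y**2 + x**2),
                      spacing=(1.5, 1.5, 1.5))


@pytest.fixture(scope="session")
def tube15():
    """Straight circular tube, radius 15 mm, length 90 mm."""
    return tube_contours(15.0, 90.0)
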