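import numpy as np
import pytest

from cbslab import coulomb, hegmp2


@pytest.fixture(scope="session")
def heg14_ecut8():
    """14-electron gas in a 2*pi-bohr box, 8 Ha cutoff (257 plane waves)."""
    return hegmp2.build_model(2 * np.pi, 8.0, 14)


@pytest.fixture(scope="session")
def heg14_series(heg14_ecut8):
    return hegmp2.mp2_correlation(heg14_ecut8)


@pytest.fixture(scope="session")
def box24_grid():
    """24-bohr cubic cell, 30 Ha cutoff: resolves sigma >= 0.45 Gaussians."""
    return coulomb.GGrid.build((24.0, 24.0, 24.0), 30.0)


@pytest.fixture(scope="session")
def box24_mt_kernel(box24_grid):
    return coulomb.kernel_values(box24_grid, coulomb.KernelSpec("mt"))
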