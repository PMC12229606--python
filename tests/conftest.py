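"""Shared fixtures.

The session-scoped MDF set uses a 400 px / 2.5 nm grid (±500 nm). MDF values
are local point evaluations, so every quantity probed at |r| ≤ ~450 nm is
identical to the package-default 1000 px grid; the smaller grid just keeps
the suite fast.
"""

import numpy as np
import pytest

from ismflux import (BackgroundModel, DetectorGeometry, GridSpec, MDFSet,
                     OpticsModel, OrbitGeometry, simulate_mdf)


@pytest.fixture(scope="session")
def optics():
    return OpticsModel()


@pytest.fixture(scope="session")
def detector():
    return DetectorGeometry()


@pytest.fixture(scope="session")
def orbit():
    return OrbitGeometry()


@pytest.fixture(scope="session")
def grid():
    return GridSpec(pixel_size=2.5, n_pixels=400)


@pytest.fixture(scope="session")
def mdf(optics, detector, orbit, grid):
    return simulate_mdf(optics, detector, orbit, grid)


@pytest.fixture(scope="session")
def bkg10():
    return BackgroundModel(10.0)


@pytest.fixture(scope="session")
def bkg3():
    return BackgroundModel(3.0)


@pytest.fixture(scope="session")
def toy_mdf():
    """A tiny 5x5-px MDF set with 3 orbit positions and 2 elements.

    Small enough for exhaustive-search oracles; values are arbitrary smooth
    positive maps.
    """
    g = GridSpec(pixel_size=2.5, n_pixels=5)
    rng = np.random.default_rng(42)
    base = rng.uniform(0.1, 1.0, size=(2, 5, 5))
    det = DetectorGeometry(n_rows=1, n_cols=2, pitch=150.0, element_size=100.0)
    orb = OrbitGeometry(L=4.0, alpha0=0.0, direction=1, n_positions=3)
    return MDFSet(base=base, grid=g, detector=det, orbit=orb)
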