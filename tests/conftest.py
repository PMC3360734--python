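import numpy as np
import pytest

import angioquant as aq

from _util import COARSE_GEOM, SMALL_GEOM, default_sprout, straight_cps


@pytest.fixture(scope="session")
def small_geom():
    return aq.make_device_geometry(SMALL_GEOM)


@pytest.fixture(scope="session")
def coarse_geom():
    return aq.make_device_geometry(COARSE_GEOM)


@pytest.fixture(scope="session")
def cps(small_geom):
    return straight_cps(small_geom)


@pytest.fixture(scope="session")
def sprout(small_geom):
    return default_sprout(small_geom)


@pytest.fixture(scope="session")
def noiseless_phantom(small_geom, cps, sprout):
    """One noiseless sprouted phantom shared by read-only tests."""
    return aq.render_stack(small_geom, cps, [sprout], None, blur_sigma_um=1.5)


@pytest.fixture(scope="session")
def noisy_phantom(small_geom, cps, sprout):
    return aq.render_stack(
        small_geom, cps, [sprout], aq.NoiseSpec(0.1, 0.05, seed=123),
        blur_sigma_um=1.5,
    )
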