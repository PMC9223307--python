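import numpy as np
import pytest

import esbalance as eb


@pytest.fixture(scope="session")
def coeffs():
    return eb.load_value_coefficients()


@pytest.fixture(scope="session")
def ref_areas():
    return eb.load_reference_areas()


@pytest.fixture(scope="session")
def ref_esv(ref_areas, coeffs):
    return eb.esv_compute(ref_areas, coeffs)


@pytest.fixture(scope="session")
def small_scene():
    """A 40×40 five-date scene with 9 zones, shared across read-only tests."""
    cfg = eb.LandscapeConfig(grid_shape=(40, 40), n_zones=9, seed=7)
    return eb.generate_scene(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240613)
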