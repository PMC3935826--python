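"""Shared fixtures: phantoms and atlases are generated once per session."""

import numpy as np
import pytest

from lesionquant import phantom

PED_GRID = (96, 96, 60)
ADULT_GRID = (96, 96, 40)


@pytest.fixture(scope="session")
def atlas_ped():
    return phantom.build_region_atlas(PED_GRID, (0.98, 0.98, 2.0))


@pytest.fixture(scope="session")
def atlas_adult():
    return phantom.build_region_atlas(ADULT_GRID, (0.98, 0.98, 3.0))


@pytest.fixture(scope="session")
def noiseless_subject():
    """Lesion-free, bias-free, noise-free adult-protocol phantom."""
    spec = phantom.PhantomSpec(
        grid_shape=ADULT_GRID, protocol=phantom.adult_protocol(noise_sigma=0.0),
        n_lesions_by_region={}, bias_field_amplitude=0.0, seed=10)
    return phantom.generate_subject(spec)


@pytest.fixture(scope="session")
def lesioned_subject():
    """Adult-protocol phantom with pontine and supratentorial lesions at the
    default noise and bias levels."""
    spec = phantom.PhantomSpec(
        grid_shape=ADULT_GRID, protocol=phantom.adult_protocol(),
        n_lesions_by_region={"pons": 1, "supratentorial": 3},
        target_t2lv_cm3=8.0, seed=21)
    return phantom.generate_subject(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
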