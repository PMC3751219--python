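import warnings

import numpy as np
import pytest

from fracvasc import phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def three_vessel_spec():
    """Three well-separated axial vessels, radius 3 voxels, noiseless."""
    vs = 21.0
    nz = 12
    vessels = [
        phantom.Vessel.axial(10.0, 10.0, 3 * vs, 0, nz - 1, label=0),
        phantom.Vessel.axial(10.0, 30.0, 3 * vs, 0, nz - 1, label=1),
        phantom.Vessel.axial(30.0, 20.0, 3 * vs, 0, nz - 1, label=2),
    ]
    return phantom.PhantomSpec(
        dims=(nz, 40, 40),
        vessels=vessels,
        bone=phantom.BoneCylinder((20.0, 20.0), 4 * vs, 2 * vs),
        limb_radius_um=18 * vs,
    )


@pytest.fixture
def deterministic_cohort_spec():
    """Noise-free cohort: exact fixed-effect time courses, no day effects."""
    return phantom.CohortSpec(
        n_animals=3,
        residual_sd=0.0,
        random_intercept_sd=0.0,
        day_multiplier_sd=0.0,
        seed=7,
    )


@pytest.fixture
def generate_quiet():
    """generate_ct_phantom with sub-resolution warnings suppressed."""

    def _gen(spec):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return phantom.generate_ct_phantom(spec)

    return _gen
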