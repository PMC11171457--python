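"""Shared fixtures: calibrated landscapes and reusable sampler runs."""

import numpy as np
import pytest

from metadf import (LandscapeParams, ModelLandscape,
                    make_glycine_landscape)


@pytest.fixture(scope="session")
def land2d():
    """Default 2-D glycine-like landscape (calibrated once per session)."""
    return make_glycine_landscape(ndim=2)


@pytest.fixture(scope="session")
def land1d():
    """Default 1-D variant."""
    return make_glycine_landscape(ndim=1)


@pytest.fixture(scope="session")
def shallow1d():
    """Shallow 1-D two-well landscape on a short domain: every feature is
    within a few kBT, so unbiased runs sample the full range."""
    params = LandscapeParams(r_c=2.0, z_wall=7.0, z_M1=2.8, z_B=3.8,
                             z_M2=4.8, d_M1=-3.0, d_M2=-1.0, b=1.0,
                             switch_on=5.5, switch_off=6.5)
    return ModelLandscape(params, ndim=1)


def flat_landscape(z_wall=7.0, switch_on=5.5, switch_off=6.5):
    """A landscape with all Gaussian amplitudes zeroed: U ≡ 0.

    Built by bypassing calibration and zeroing the amplitudes; the public
    constructor (rightly) refuses depth-zero wells.
    """
    params = LandscapeParams(r_c=2.0, z_wall=z_wall, z_M1=2.8, z_B=3.8,
                             z_M2=4.8, d_M1=-3.0, d_M2=-1.0, b=1.0,
                             switch_on=switch_on, switch_off=switch_off)
    land = ModelLandscape.__new__(ModelLandscape)
    land.params = params
    land.ndim = 1
    land.temperature = 300.0
    land.functional_form = "gaussian-wells+switch"
    land._centers = np.array([params.z_M1, params.z_B, params.z_M2])
    land._widths = np.array([params.w_M1, params.w_B, params.w_M2])
    land._amps = np.zeros(3)
    return land


def single_well_landscape(depth=1000.0, width=1.0, center=2.8,
                          z_wall=10.0):
    """Single deep Gaussian well (near-harmonic at the bottom with
    stiffness depth/width²), again via amplitude override."""
    params = LandscapeParams(r_c=1.0, z_wall=z_wall, z_M1=center,
                             z_B=center + 1.4, z_M2=center + 2.4,
                             d_M1=-depth, d_M2=-1e-3, b=1e-3,
                             w_M1=width)
    land = ModelLandscape.__new__(ModelLandscape)
    land.params = params
    land.ndim = 1
    land.temperature = 300.0
    land.functional_form = "gaussian-wells+switch"
    land._centers = np.array([params.z_M1, params.z_B, params.z_M2])
    land._widths = np.array([params.w_M1, params.w_B, params.w_M2])
    land._amps = np.array([-depth, 0.0, 0.0])
    return land
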