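"""Shared fixtures: expensive Monte Carlo runs are simulated once per session."""

import numpy as np
import pytest

import turbidslab as ts


@pytest.fixture(scope="session")
def homog_mc_result():
    """Non-absorbing homogeneous slab (L=203 um, n=1.52, isotropic l_t=25.5 um).

    The reference configuration whose simulated decay time and width slope
    reproduce the measured ones without absorption.
    """
    scn = ts.make_scenario("homogeneous_203um")
    return ts.run_simulation(scn.slab, 4_000_000, 101, scn.binning)


@pytest.fixture(scope="session")
def layered_result():
    """Symmetric 5-layer stack (22/60/26/60/22 um; l_t 11/21.5/3.5 um, n=1.52)."""
    slab = ts.symmetric_five_layer((22.0, 60.0, 26.0), (11.0, 21.5, 3.5),
                                   n=1.52)
    return ts.run_simulation(slab, 1_000_000, 102,
                             ts.BinningSpec(t_max=80.0, record_frames=False))


@pytest.fixture(scope="session")
def membrane_cuts():
    """Synthetic membrane cross-cut dataset at the known truth (g=0.7, l_s=150)."""
    scn = ts.make_scenario("membrane_85um")
    res = ts.run_simulation(scn.slab, 10_000_000, 103, scn.binning)
    stack = ts.synthesize_frame_stack(res, scn, 104)
    return ts.synthesize_crosscuts(stack), scn


@pytest.fixture()
def gaussian_frame():
    """Isotropic Gaussian intensity map on a fine grid (sigma = 120 um)."""
    x = np.linspace(-1500.0, 1500.0, 301)
    X, Y = np.meshgrid(x, x)
    sigma = 120.0
    frame = np.exp(-(X**2 + Y**2) / (2 * sigma**2))
    return frame, x, sigma
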