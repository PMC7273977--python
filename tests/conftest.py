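"""Shared fixtures: toy geometries, phantoms and reusable long runs.

The expensive driver runs (hundreds of EM iterations) are session-scoped
so several behavioural tests can share one reconstruction.
"""

from __future__ import annotations

import numpy as np
import pytest

import bootrecon as br
from bootrecon.hyperopt import DriverConfig, reconstruct_bootstrap_optimised
from bootrecon.penalties import make_context, uniform_weights
from bootrecon.projector import Geometry, desk_geometry, forward_project, sensitivity_image


@pytest.fixture(scope="session")
def toy_geom() -> Geometry:
    """8x8 image, 10 angles x 12 bins: small enough for brute-force oracles."""
    return Geometry(n_angles=10, n_bins=12, bin_size=2.0, image_shape=(8, 8), pixel_size=2.0)


@pytest.fixture(scope="session")
def toy_counts(toy_geom):
    """Self-consistent toy Poisson data (m, b, true image) on the 8x8 grid."""
    rng = np.random.default_rng(3)
    truth = np.zeros((8, 8))
    truth[2:6, 2:6] = 4.0
    truth[3:5, 3:5] = 8.0
    mean = forward_project(truth, toy_geom) * 5 + 2.0
    m = rng.poisson(mean).astype(np.int64)
    b = np.full(toy_geom.sino_shape, 2.0)
    return m, b, truth


@pytest.fixture(scope="session")
def toy_ctx(toy_geom):
    wm = uniform_weights(toy_geom.image_shape, stencil=3)
    return make_context(wm, sensitivity_image(toy_geom))


@pytest.fixture(scope="session")
def desk() -> Geometry:
    return desk_geometry(psf_fwhm=3.0)


@pytest.fixture(scope="session")
def brain_phantom(desk):
    return br.make_phantom("brain_like", desk.image_shape, desk.pixel_size, seed=0)


@pytest.fixture(scope="session")
def desk_ctx(desk):
    wm = uniform_weights(desk.image_shape, stencil=5)
    return make_context(wm, sensitivity_image(desk))


@pytest.fixture(scope="session")
def mid_dataset(desk, brain_phantom):
    spec = br.AcquisitionSpec(total_counts_mean=3.5e6, seed=1)
    return br.simulate_acquisition(brain_phantom, desk, spec)


@pytest.fixture(scope="session")
def long_driver_run(desk, desk_ctx, mid_dataset):
    """Bootstrap-optimised run driven to convergence (30 N iterations)."""
    cfg = DriverConfig(lambda0=1000.0, N=30, max_iter=900, seed=2)
    return reconstruct_bootstrap_optimised(mid_dataset.m, mid_dataset.b, desk, desk_ctx, cfg)


@pytest.fixture(scope="session")
def count_level_betas(desk, desk_ctx, brain_phantom):
    """Final beta_use per count level over 5 noise realisations each."""
    out: dict[float, list[float]] = {}
    for counts in (3.5e5, 3.5e6, 3.5e7):
        finals = []
        for s in range(5):
            spec = br.AcquisitionSpec(total_counts_mean=counts, seed=10 + s)
            ds = br.simulate_acquisition(brain_phantom, desk, spec)
            cfg = DriverConfig(lambda0=1000.0, N=30, max_iter=120, seed=20 + s)
            res = reconstruct_bootstrap_optimised(ds.m, ds.b, desk, desk_ctx, cfg)
            finals.append(res.beta_trace.beta_use[-1])
        out[counts] = finals
    return out
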