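"""Shared fixtures.

Heavy artifacts (planted datasets, the trained melting-series VAE) are
session-scoped so the acceptance-style tests can share them.
"""

from __future__ import annotations

import numpy as np
import pytest

from spihetero import datasets, refmatch, simulate, vae
from spihetero.geometry import make_geometry


@pytest.fixture(scope="session")
def geom64():
    return make_geometry(n=64)


@pytest.fixture(scope="session")
def geom32():
    return make_geometry(n=32)


@pytest.fixture(scope="session")
def geom32_clean():
    """32-pixel geometry without mask features (for oracle tests)."""
    return make_geometry(n=32, beamstop_radius_frac=0.0, gap_rows=None)


@pytest.fixture(scope="session")
def cube_volume(geom64):
    return simulate.reference_cube_volume(geometry=geom64)


@pytest.fixture(scope="session")
def sphere_volume(geom64):
    return simulate.superball_volume(simulate.morph_spec(1.0), geometry=geom64)


@pytest.fixture(scope="session")
def melting_data(geom64):
    """400 synthetic melting-series averages with ground truth."""
    return datasets.melting_series_averages(400, geom64, seed=11, n_morphs=40)


@pytest.fixture(scope="session")
def melting_estimates(geom64, melting_data, cube_volume):
    avgs, _ = melting_data
    grid = refmatch.build_quaternion_grid(16, "O")
    return refmatch.estimate_orientations(avgs, cube_volume, grid, geom64)


@pytest.fixture(scope="session")
def melting_vae(geom64, melting_data, melting_estimates):
    """1D-latent VAE trained on the melting series (the heavy fixture)."""
    avgs, _ = melting_data
    inputs, pre = vae.preprocess(avgs, geom64, melting_estimates, downsample=2)
    model = vae.train(
        inputs, pre, latent_dim=1, epochs=200, beta=1.0, seed=3, batch_size=100,
        n_restarts=2,
    )
    return model


@pytest.fixture(scope="session")
def zoo_data(geom64):
    """Four-shape planted ensemble: cubes, spheres, ellipsoids, dimers."""
    return datasets.shape_zoo_averages(20, geom64, seed=7)


def assert_allclose(a, b, **kw):
    np.testing.assert_allclose(a, b, **kw)
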