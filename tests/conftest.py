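"""Shared fixtures: small phantom specs and deterministic random fields."""

import numpy as np
import pytest
from scipy import ndimage

from tmplkit.core_io import Volume, default_affine
from tmplkit.phantoms import PhantomSpec
from tmplkit.registration import VelocityField


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_spec():
    """32^3 at 6 mm: full head in the field of view, seconds-scale operations."""
    return PhantomSpec(grid_shape=(32, 32, 32), spacing_mm=6.0,
                       strata=[("60-64", 1, 1)])


@pytest.fixture
def clean_tiny_spec():
    """Noise-, bias- and warp-free variant for exactness checks."""
    return PhantomSpec(grid_shape=(32, 32, 32), spacing_mm=6.0,
                       strata=[("60-64", 1, 1)], warp_sd_mm=0.0,
                       noise_sd=0.0, bias_amplitude=0.0)


@pytest.fixture
def desk_spec():
    """48^3 at 4 mm: the scale used for template-building tests."""
    return PhantomSpec(grid_shape=(48, 48, 48), spacing_mm=4.0,
                       strata=[("60-64", 2, 2)])


def smooth_velocity(shape, spacing, sigma_vox, max_vox, seed):
    """Gaussian-smoothed white-noise velocity with a set maximum magnitude."""
    rng = np.random.default_rng(seed)
    v = np.stack([ndimage.gaussian_filter(rng.standard_normal(shape), sigma_vox)
                  for _ in range(3)])
    v *= max_vox / np.sqrt((v ** 2).sum(axis=0)).max()
    return VelocityField(v, spacing, default_affine(spacing, shape))


@pytest.fixture
def random_velocity():
    return smooth_velocity((24, 24, 24), (2.0, 2.0, 2.0), sigma_vox=4.0,
                           max_vox=2.0, seed=7)


def ellipsoid_volume(shape=(32, 32, 32), spacing=(6.0,) * 3,
                     semi_axes_mm=(81.0, 66.0, 50.0), value=1.0):
    idx = np.indices(shape, dtype=float)
    centre = (np.asarray(shape, float) - 1) / 2
    r2 = sum(((idx[a] - centre[a]) * spacing[a] / semi_axes_mm[a]) ** 2 for a in range(3))
    return Volume((r2 <= 1.0) * value, spacing, default_affine(spacing, shape))
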