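"""Shared fixtures: phantom subjects and small geometric volumes.

Expensive phantom rasterisations are session-scoped so the suite pays for
each of them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from hippoprof import (
    ImageVolume,
    PhantomSpec,
    make_subject,
)
from hippoprof.phantom import default_t1_grid


@pytest.fixture(scope="session")
def t1_grid() -> ImageVolume:
    return default_t1_grid()


@pytest.fixture(scope="session")
def base_subject():
    """Canonical unposed phantom subject with images."""
    return make_subject(PhantomSpec(seed=3), subject_id="base")


@pytest.fixture(scope="session")
def noiseless_subject():
    """Unposed phantom without any noise, T2 = 115 ms (closed-form oracle)."""
    spec = PhantomSpec(seed=3, noise_sd=0.0, t1_noise_sd=0.0, t2_tissue=115.0)
    return make_subject(spec, subject_id="noiseless")


@pytest.fixture(scope="session")
def ellipsoid_subject():
    """Discretised ellipsoid phantom (semi-axes 25/10/8 mm, 1-mm grid)."""
    return make_subject(PhantomSpec(shape="ellipsoid", seed=1),
                        subject_id="ellipsoid", with_images=False)


def smooth_volume(shape=(40, 40, 40), spacing=(1.0, 1.0, 1.0)) -> ImageVolume:
    """Band-limited scalar volume for interpolation round-trip tests."""
    affine = np.diag([*spacing, 1.0])
    affine[:3, 3] = -(np.asarray(shape) - 1) * np.asarray(spacing) / 2
    idx = np.indices(shape, dtype=float)
    world = np.einsum("ab,b...->a...", affine[:3, :3], idx) + \
        affine[:3, 3][:, None, None, None]
    x, y, z = world
    data = (np.sin(2 * np.pi * x / 23.0) + np.cos(2 * np.pi * y / 31.0)
            + np.sin(2 * np.pi * z / 27.0) + 3.0)
    return ImageVolume(data, affine)


@pytest.fixture(scope="session")
def smooth_vol() -> ImageVolume:
    return smooth_volume()
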