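"""Shared fixtures.

The default-phantom reconstruction (128x256x128 voxels, 91 angles, 25 SIRT
iterations) takes ~30 s, so it is built once per session and shared by every
test that exercises the full pipeline.
"""

import numpy as np
import pytest

from osteotomo import PhantomSpec, build_phantom
from osteotomo.pipeline import reconstruct_phantom


@pytest.fixture(scope="session")
def default_pipeline():
    """(reconstruction, density, truth, spec) for the default phantom, seed 1,
    noiseless +/-90 deg / 2 deg series, SIRT 25 iterations."""
    spec = PhantomSpec(seed=1)
    vol, density, truth = reconstruct_phantom(spec)
    return vol, density, truth, spec


@pytest.fixture(scope="session")
def small_phantom():
    """A cheap 64^3 phantom for projection/alignment tests."""
    spec = PhantomSpec(
        volume_shape=(64, 64, 64),
        rod_radius_top=22.0,
        rod_radius_bottom=26.0,
        fibril_fill_fraction=0.25,
        plate_density_per_fibril=1,
        seed=3,
    )
    density, elements, truth = build_phantom(spec)
    return density, elements, truth, spec


def two_cylinder_volume(n=64, voxel=1.0):
    """Two parallel cylinders of different densities in an n^3 volume."""
    data = np.zeros((n, n, n), dtype=np.float32)
    x = np.arange(n) - (n - 1) / 2.0
    xx, zz = np.meshgrid(x, x, indexing="ij")
    c1 = (xx + n * 0.18) ** 2 + (zz + n * 0.10) ** 2 <= (n * 0.12) ** 2
    c2 = (xx - n * 0.16) ** 2 + (zz - n * 0.14) ** 2 <= (n * 0.17) ** 2
    data[c1[:, None, :].repeat(n, axis=1)] = 1.0
    data[c2[:, None, :].repeat(n, axis=1)] = 0.6
    return data
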