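"""Shared fixtures: seeded RNGs, random geometries, blob masks."""

import numpy as np
import pytest
from scipy import ndimage

from lesiontrack.geometry import ImageGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_geometry(
    n_cols=32, n_rows=32, n_slices=8,
    col_spacing=1.0, row_spacing=1.0, slice_spacing=2.5,
    origin=(0.0, 0.0, 0.0), rotation=None,
):
    kwargs = {}
    if rotation is not None:
        kwargs = dict(row_dir=rotation[:, 0], col_dir=rotation[:, 1],
                      slice_dir=rotation[:, 2])
    return ImageGeometry(
        n_cols=n_cols, n_rows=n_rows, n_slices=n_slices,
        col_spacing=col_spacing, row_spacing=row_spacing,
        slice_spacing=slice_spacing, slice_thickness=slice_spacing,
        origin=np.asarray(origin, dtype=float), **kwargs,
    )


def random_rotation(rng):
    """Uniform random proper rotation matrix (QR with sign fix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 2] *= -1
    return q


def random_blob_slice(rng, shape=(32, 32), smoothing=2.0, density=0.5):
    """Random connected-ish binary slice from thresholded smoothed noise."""
    noise = ndimage.gaussian_filter(rng.normal(size=shape), smoothing)
    cut = np.quantile(noise, 1.0 - density * rng.uniform(0.2, 1.0))
    return (noise > cut).astype(np.uint8)


def random_blob_volume(rng, shape=(8, 32, 32), smoothing=2.0, density=0.3):
    noise = ndimage.gaussian_filter(rng.normal(size=shape), smoothing)
    cut = np.quantile(noise, 1.0 - density)
    return (noise > cut).astype(np.uint8)


@pytest.fixture
def geometry():
    return make_geometry()
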