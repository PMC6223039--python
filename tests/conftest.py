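import numpy as np
import pytest

from nucarch.core import GridSpec, NuclearMask
from nucarch.synthetic import (
    NoiseParams,
    NucleusShapeParams,
    SceneConfig,
    make_nucleus_mask,
    render_scene,
)


@pytest.fixture(scope="session")
def iso_grid_fine():
    """Isotropic 0.125 µm grid large enough for a 3 µm-radius sphere."""
    return GridSpec((52, 52, 52), (0.125, 0.125, 0.125))


@pytest.fixture(scope="session")
def sphere_mask(iso_grid_fine):
    return make_nucleus_mask(NucleusShapeParams(radius=3.0), iso_grid_fine, seed=0)


@pytest.fixture(scope="session")
def noiseless_scene():
    """Default scene (4 µm homolog separation), rendered without noise."""
    cfg = SceneConfig(noise=NoiseParams())
    volume, truth = render_scene(cfg, seed=7)
    return cfg, volume, truth


def mask_from_voxels(voxels, shape, spacing):
    """Build a NuclearMask from explicit voxel indices."""
    m = np.zeros(shape, dtype=bool)
    m[tuple(np.asarray(voxels).T)] = True
    return NuclearMask(mask=m, grid=GridSpec(shape, spacing))


def random_blob_mask(rng, shape=(10, 10, 10), spacing=(0.5, 0.25, 0.25)):
    """Random connected-ish blob: a dilated set of random seed voxels."""
    from scipy import ndimage

    m = np.zeros(shape, dtype=bool)
    n_seeds = rng.integers(1, 6)
    idx = rng.integers(2, np.asarray(shape) - 2, size=(n_seeds, 3))
    m[tuple(idx.T)] = True
    m = ndimage.binary_dilation(m, iterations=int(rng.integers(1, 3)))
    return NuclearMask(mask=m, grid=GridSpec(shape, spacing))
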