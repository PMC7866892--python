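import numpy as np
import pytest

from bfmap import VolumeStack


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def stack_from_samples(samples, shape=None):
    """Build a VolumeStack whose voxels hold the given per-voxel samples.

    ``samples`` is (n_subjects, n_voxels); the grid is (n_voxels, 1, 1)
    unless a 3-D shape is given.
    """
    samples = np.asarray(samples, dtype=float)
    n, v = samples.shape
    if shape is None:
        shape = (v, 1, 1)
    data = samples.reshape(n, *shape)
    return VolumeStack(data=data, mask=np.ones(shape, dtype=bool),
                       affine=np.eye(4))
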