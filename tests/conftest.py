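import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.spatial.distance import cdist

from vdmap import LabeledVolume, VoxelGrid

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20250924)


def random_label_volume(rng, shape, spacing, n_labels=3, density=0.05):
    """Sparse random label volume guaranteeing every label has >= 1 voxel."""
    voxels = np.zeros(shape, dtype=np.int32)
    flat = voxels.reshape(-1)
    n = max(n_labels, int(density * flat.size))
    idx = rng.choice(flat.size, size=n, replace=False)
    flat[idx] = rng.integers(1, n_labels + 1, size=n)
    for vid in range(1, n_labels + 1):  # force presence
        flat[idx[vid - 1]] = vid
    return LabeledVolume(VoxelGrid(shape, spacing), voxels)


def brute_force_distance(volume, vessel_id):
    """Independent oracle: min pairwise mm distance to the vessel's voxel centers."""
    centers = volume.grid.voxel_centers().reshape(-1, 3)
    sources = centers[(volume.voxels == vessel_id).reshape(-1)]
    if len(sources) == 0:
        return np.full(volume.grid.shape, np.inf)
    return cdist(centers, sources).min(axis=1).reshape(volume.grid.shape)
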