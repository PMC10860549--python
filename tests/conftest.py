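import numpy as np
import pytest
from scipy.spatial.distance import cdist

from bwdose.geometry import StructureMask


def brute_force_expand(mask: StructureMask, margin_mm: float) -> np.ndarray:
    """O(N*M) all-pairs physical-distance expansion oracle."""
    shape = mask.occupancy.shape
    spacing = np.asarray(mask.spacing_mm)
    centers = np.indices(shape).reshape(3, -1).T * spacing
    struct = centers[mask.occupancy.ravel()]
    if len(struct) == 0:
        return mask.occupancy.copy()
    d = cdist(centers, struct).min(axis=1)
    return (d <= margin_mm).reshape(shape)


def brute_force_contract(mask: StructureMask, margin_mm: float) -> np.ndarray:
    """Keep voxels strictly farther than margin from the complement."""
    shape = mask.occupancy.shape
    spacing = np.asarray(mask.spacing_mm)
    centers = np.indices(shape).reshape(3, -1).T * spacing
    comp = centers[~mask.occupancy.ravel()]
    if len(comp) == 0:
        return mask.occupancy.copy()
    d = cdist(centers, comp).min(axis=1)
    return ((d > margin_mm) & mask.occupancy.ravel()).reshape(shape)


@pytest.fixture
def rng():
    return np.random.default_rng(20231)


@pytest.fixture
def random_mask(rng):
    def make(shape=(8, 10, 9), spacing=(3.0, 1.5, 2.0), density=0.2, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        occ = r.random(shape) < density
        return StructureMask(occ, spacing, label="random")
    return make


def voxel_sphere(radius_mm: float, spacing=(1.0, 1.0, 1.0), pad_mm: float = 6.0):
    """Voxelized sphere centered in its grid."""
    spacing = np.asarray(spacing, dtype=float)
    half = radius_mm + pad_mm
    shape = (2 * np.ceil(half / spacing) + 1).astype(int)
    center = (shape - 1) / 2.0 * spacing
    zz, yy, xx = [np.arange(n) * s for n, s in zip(shape, spacing)]
    grid = np.meshgrid(zz, yy, xx, indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grid, center))
    return StructureMask(d2 <= radius_mm**2, tuple(spacing), label="sphere")
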