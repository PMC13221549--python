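import numpy as np
import pytest

from lutidose import OrganMask, VolumeGrid


def make_sphere_mask(radius_mm, spacing=(3.0, 3.0, 3.0), organ="liver",
                     pad_vox=4, source="reference"):
    """Voxelized sphere centered on the grid, world origin at voxel (0,0,0)."""
    spacing = np.asarray(spacing, dtype=float)
    n = (2 * np.ceil(radius_mm / spacing).astype(int) + 1) + 2 * pad_vox
    center = (n - 1) / 2.0 * spacing
    grids = np.ogrid[: n[0], : n[1], : n[2]]
    r2 = sum(((grids[ax] * spacing[ax] - center[ax]) ** 2) for ax in range(3))
    return OrganMask(values=r2 <= radius_mm**2, spacing=tuple(spacing),
                     organ=organ, source=source)


def mask_from_array(values, spacing=(1.0, 1.0, 1.0), organ="liver"):
    return OrganMask(values=np.asarray(values, dtype=bool), spacing=spacing,
                     organ=organ, absent=not np.asarray(values).any())


def brute_force_boundary(values, spacing):
    """Independent 6-neighbour boundary oracle: explicit neighbour checks."""
    pts = []
    shape = values.shape
    for i, j, k in np.argwhere(values):
        on_boundary = False
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)):
            ni, nj, nk = i + di, j + dj, k + dk
            if not (0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]):
                on_boundary = True
                break
            if not values[ni, nj, nk]:
                on_boundary = True
                break
        if on_boundary:
            pts.append((i * spacing[0], j * spacing[1], k * spacing[2]))
    return np.asarray(pts, dtype=float)


def brute_force_hd_mda(a_values, b_values, spacing):
    """All-pairs Euclidean oracle for HD and pooled MDA, in mm."""
    from scipy.spatial.distance import cdist

    pa = brute_force_boundary(a_values, spacing)
    pb = brute_force_boundary(b_values, spacing)
    d = cdist(pa, pb)
    d_ab = d.min(axis=1)
    d_ba = d.min(axis=0)
    hd = max(d_ab.max(), d_ba.max())
    mda = (d_ab.sum() + d_ba.sum()) / (len(d_ab) + len(d_ba))
    return float(hd), float(mda)


def random_mask_pair(rng, max_side=12):
    """Random overlapping-ish mask pair on a small anisotropic lattice."""
    shape = tuple(int(rng.integers(3, max_side + 1)) for _ in range(3))
    spacing = tuple(float(rng.uniform(0.5, 3.0)) for _ in range(3))
    a = rng.random(shape) < rng.uniform(0.1, 0.6)
    b = rng.random(shape) < rng.uniform(0.1, 0.6)
    if not a.any():
        a[tuple(int(rng.integers(0, s)) for s in shape)] = True
    if not b.any():
        b[tuple(int(rng.integers(0, s)) for s in shape)] = True
    return (mask_from_array(a, spacing), mask_from_array(b, spacing))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_volume():
    values = np.arange(4 * 4 * 4, dtype=float).reshape(4, 4, 4)
    return VolumeGrid(values=values, spacing=(1.5, 1.37, 1.37), quantity="HU")
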