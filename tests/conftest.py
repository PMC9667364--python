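import numpy as np
import pytest

import lenshape as ls


@pytest.fixture(scope="session")
def sphere_phantom():
    """Voxelized solid sphere, r = 40 voxels on a 96^3 grid, 0.01 mm voxels."""
    volume, truth = ls.make_phantom(ls.PhantomSpec())
    return volume, truth


@pytest.fixture(scope="session")
def ellipsoid_phantom():
    """Solid ellipsoid with semi-axes (40, 20, 20) voxels."""
    volume, truth = ls.make_phantom(
        ls.PhantomSpec(shape="ellipsoid", semi_axes=(40.0, 20.0, 20.0)))
    return volume, truth


@pytest.fixture(scope="session")
def tree64():
    return ls.make_tree(64, seed=1)


@pytest.fixture(scope="session")
def tree126():
    return ls.make_tree(126, seed=3)


@pytest.fixture(scope="session")
def default_study(tree126):
    table, truth = ls.make_study(ls.StudySpec(seed=3), tree126)
    return table, truth


def brute_force_covariance(volume, label):
    """Two-pass covariance over all voxel centers, written independently of
    the implementation (explicit accumulation, no np.cov)."""
    idx = np.argwhere(volume.grid == label).astype(float)
    pts = (idx + 0.5) * np.asarray(volume.spacing)
    n = pts.shape[0]
    mean = pts.sum(axis=0) / n
    acc = np.zeros((3, 3))
    for chunk in np.array_split(pts, max(n // 65536, 1)):
        d = chunk - mean
        acc += d.T @ d
    return acc / n
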