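"""Shape-metric correctness against analytic and brute-force oracles.

The uniform solid ellipsoid with semi-axes (a, b, c) has point covariance
diag(a^2, b^2, c^2) / 5, which fixes every eigenvalue ratio in closed form;
spheres and cubes give closed-form sphericity targets.
"""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lenshape as ls
from lenshape.metrics import extract_surface_mesh, sphericity_from
from lenshape.volume import DegenerateGeometryError

from conftest import brute_force_covariance


def test_covariance_matches_brute_force(ellipsoid_phantom):
    vol, _ = ellipsoid_phantom
    from lenshape.metrics import covariance_matrix
    ours = covariance_matrix(vol, 1)
    brute = brute_force_covariance(vol, 1)
    assert np.allclose(ours, brute, rtol=1e-9, atol=0)


def test_sphere_eigenvalues_symmetric(sphere_phantom):
    vol, _ = sphere_phantom
    e = ls.covariance_eigenvalues(vol, 1)
    assert e.l1 / e.l3 == pytest.approx(1.0, rel=0.01)
    assert not e.degenerate


def test_ellipsoid_eigenvalue_ratios(ellipsoid_phantom):
    vol, truth = ellipsoid_phantom
    e = ls.covariance_eigenvalues(vol, 1)
    # analytic: eigenvalues proportional to (40^2, 20^2, 20^2)/5
    assert e.l2 / e.l1 == pytest.approx(0.25, rel=0.02)
    assert e.l3 / e.l2 == pytest.approx(1.0, rel=0.02)
    expected = truth["covariance_eigenvalues_mm2"]
    for got, want in zip((e.l1, e.l2, e.l3), expected):
        assert got == pytest.approx(want, rel=0.02)


def test_rotation_invariance_of_eigenvalues():
    base, _ = ls.make_phantom(ls.PhantomSpec(shape="ellipsoid",
                                             semi_axes=(40.0, 20.0, 20.0)))
    rot, _ = ls.make_phantom(ls.PhantomSpec(shape="ellipsoid",
                                            semi_axes=(40.0, 20.0, 20.0),
                                            orientation=(0.0, np.pi / 6, 0.0)))
    e0 = ls.covariance_eigenvalues(base, 1)
    e1 = ls.covariance_eigenvalues(rot, 1)
    for a, b in zip((e0.l1, e0.l2, e0.l3), (e1.l1, e1.l2, e1.l3)):
        assert b == pytest.approx(a, rel=0.01)


def test_axis_permutation_invariance(ellipsoid_phantom):
    vol, _ = ellipsoid_phantom
    swapped = ls.VoxelVolume(grid=np.transpose(vol.grid, (2, 0, 1)),
                             spacing=vol.spacing)
    e0 = ls.covariance_eigenvalues(vol, 1)
    e1 = ls.covariance_eigenvalues(swapped, 1)
    assert (e1.l1, e1.l2, e1.l3) == pytest.approx((e0.l1, e0.l2, e0.l3))


def test_sphere_shape_metrics(sphere_phantom):
    vol, _ = sphere_phantom
    m = ls.compute_shape_metrics(vol, 1)
    assert m.anisotropy == pytest.approx(0.0, abs=0.02)
    assert m.flatness == pytest.approx(1.0, abs=0.02)
    assert m.elongation == pytest.approx(1.0, abs=0.02)
    assert m.sphericity == pytest.approx(1.0, abs=0.02)


def test_flattened_spheroid_loads_on_anisotropy():
    # (r/2, r, r): the two long axes tie, so elongation (l2/l1) stays 1 and
    # the flattening shows up in anisotropy and flatness.
    vol, _ = ls.make_phantom(ls.PhantomSpec(shape="ellipsoid",
                                            semi_axes=(20.0, 40.0, 40.0)))
    m = ls.compute_shape_metrics(vol, 1)
    assert m.anisotropy == pytest.approx(0.75, abs=0.02)
    assert m.elongation == pytest.approx(1.0, abs=0.02)
    assert m.flatness == pytest.approx(0.25, abs=0.02)


@given(st.floats(0.05, 1.0), st.floats(0.05, 1.0))
@settings(max_examples=50, deadline=None)
def test_anisotropy_identity(ratio21, ratio32):
    """anisotropy == 1 - flatness * elongation for any eigenvalue triple."""
    l1 = 1.0
    l2 = ratio21 * l1
    l3 = ratio32 * l2
    e = ls.EigenTriple(l1, l2, l3)
    assert e.anisotropy == pytest.approx(1.0 - e.flatness * e.elongation,
                                         abs=1e-12)


def test_scale_invariance_of_shape(sphere_phantom):
    vol, _ = sphere_phantom
    doubled = ls.VoxelVolume(grid=vol.grid, spacing=tuple(2 * s for s in vol.spacing))
    m1 = ls.compute_shape_metrics(vol, 1)
    m2 = ls.compute_shape_metrics(doubled, 1)
    assert m2.anisotropy == pytest.approx(m1.anisotropy, abs=1e-12)
    assert m2.flatness == pytest.approx(m1.flatness, abs=1e-12)
    assert m2.elongation == pytest.approx(m1.elongation, abs=1e-12)
    assert m2.sphericity == pytest.approx(m1.sphericity, rel=1e-9)
    assert m2.volume_mm3 == pytest.approx(8 * m1.volume_mm3, rel=1e-12)
    assert m2.surface_area_mm2 == pytest.approx(4 * m1.surface_area_mm2, rel=1e-9)


def test_progressive_flattening_is_monotone():
    """Anisotropy rises and sphericity falls as a spheroid flattens."""
    anis, sph = [], []
    for ap in (36.0, 30.0, 24.0, 18.0, 12.0):
        vol, _ = ls.make_phantom(ls.PhantomSpec(
            shape="ellipsoid", semi_axes=(ap, 36.0, 36.0), grid_size=88))
        m = ls.compute_shape_metrics(vol, 1)
        anis.append(m.anisotropy)
        sph.append(m.sphericity)
    assert all(b > a for a, b in zip(anis, anis[1:]))
    assert all(b < a for a, b in zip(sph, sph[1:]))


@pytest.mark.parametrize("edge", [20, 40])
def test_cube_sphericity_converges(edge):
    """A cube's sphericity approaches (pi/6)^(1/3) ~ 0.806 with resolution."""
    g = edge + 8
    grid = np.zeros((g, g, g), dtype=np.uint8)
    grid[4:4 + edge, 4:4 + edge, 4:4 + edge] = 1
    vol = ls.VoxelVolume(grid=grid, spacing=(0.01,) * 3)
    target = (np.pi / 6) ** (1 / 3)
    # Unsmoothed: exact voxel geometry, V = s^3 and A = 6 s^2 up to mesh
    # discretization of the flat faces.
    mesh = extract_surface_mesh(vol, 1, smoothing=0)
    sph = sphericity_from(ls.metrics.label_volume_mm3(vol, 1), mesh.area)
    tol = 0.06 if edge == 20 else 0.03
    assert sph == pytest.approx(target, rel=tol)


def test_sphere_mesh_area(sphere_phantom):
    vol, truth = sphere_phantom
    analytic = truth["surface_area_mm2"]
    rough = extract_surface_mesh(vol, 1, smoothing=0)
    smooth = extract_surface_mesh(vol, 1, smoothing=20)
    assert rough.is_closed and smooth.is_closed
    assert rough.area == pytest.approx(analytic, rel=0.10)
    assert smooth.area == pytest.approx(analytic, rel=0.02)


def test_boundary_touching_label_still_closed():
    grid = np.zeros((16, 16, 16), dtype=np.uint8)
    grid[0:8, 4:12, 4:12] = 1  # touches the z=0 face
    vol = ls.VoxelVolume(grid=grid, spacing=(0.01,) * 3)
    mesh = extract_surface_mesh(vol, 1, smoothing=0)
    assert mesh.is_closed


def test_single_voxel_label_mesh():
    grid = np.zeros((6, 6, 6), dtype=np.uint8)
    grid[3, 3, 3] = 1
    vol = ls.VoxelVolume(grid=grid, spacing=(0.01,) * 3)
    mesh = extract_surface_mesh(vol, 1, smoothing=0)
    assert mesh.is_closed and mesh.area > 0


def test_multiple_components_keep_largest(caplog):
    import logging
    grid = np.zeros((24, 24, 24), dtype=np.uint8)
    grid[2:12, 2:12, 2:12] = 1      # 1000 voxels
    grid[18:21, 18:21, 18:21] = 1   # 27 voxels, disconnected
    vol = ls.VoxelVolume(grid=grid, spacing=(0.01,) * 3)
    with caplog.at_level(logging.WARNING):
        mesh = extract_surface_mesh(vol, 1, smoothing=0)
    assert any("connected components" in r.message for r in caplog.records)
    # Area should be close to the large cube alone (6 * (0.1 mm)^2).
    assert mesh.area == pytest.approx(6 * 0.1 ** 2, rel=0.15)


def test_degenerate_labels_raise():
    grid = np.zeros((8, 8, 8), dtype=np.uint8)
    grid[2, 2, 2:5] = 1  # 3 collinear voxels
    vol = ls.VoxelVolume(grid=grid, spacing=(0.01,) * 3)
    with pytest.raises(DegenerateGeometryError):
        ls.covariance_eigenvalues(vol, 1)
    grid2 = np.zeros((8, 8, 8), dtype=np.uint8)
    grid2[2, 2:6, 2:6] = 1  # coplanar sheet
    vol2 = ls.VoxelVolume(grid=grid2, spacing=(0.01,) * 3)
    e = ls.covariance_eigenvalues(vol2, 1)
    assert e.degenerate and e.l3 == pytest.approx(0.0, abs=1e-15)
    with pytest.raises(DegenerateGeometryError):
        ls.compute_shape_metrics(vol2, 1)


def test_transverse_diameter_sphere(sphere_phantom):
    vol, _ = sphere_phantom
    d = ls.transverse_diameter(vol, 1, "naso-temporal")
    assert abs(d - 0.80) <= 0.01 + 1e-12  # within one voxel


def test_transverse_diameter_ellipsoid_axes():
    vol, _ = ls.make_phantom(ls.PhantomSpec(shape="ellipsoid",
                                            semi_axes=(20.0, 30.0, 40.0)))
    for axis, semi in zip(("anterior-posterior", "dorso-ventral", "naso-temporal"),
                          (20, 30, 40)):
        d = ls.transverse_diameter(vol, 1, axis)
        assert abs(d - 2 * semi * 0.01) <= 0.01 + 1e-12


def test_two_eye_average():
    grid = np.zeros((32, 32, 32), dtype=np.uint8)
    grid[4:12, 4:12, 4:12] = 1    # label 1: 8 voxels wide
    grid[20:28, 20:28, 16:28] = 2  # label 2: 12 voxels wide
    vol = ls.VoxelVolume(grid=grid, spacing=(0.01,) * 3)
    d1 = ls.transverse_diameter(vol, 1)
    d2 = ls.transverse_diameter(vol, 2)
    assert ls.mean_diameter(vol, [1, 2]) == pytest.approx((d1 + d2) / 2)
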