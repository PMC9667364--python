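"""3D lens-shape metrics from segmented voxel volumes.

Four scale-free descriptors quantify deviation from a perfect sphere:

* **anisotropy** ``1 - l3/l1`` — 0 for a sphere, approaching 1 for extreme
  flattening or elongation;
* **flatness** ``l3/l2`` and **elongation** ``l2/l1`` — both 1 for a sphere;
* **sphericity** — surface area of the equal-volume sphere divided by the
  measured surface area, 1 for a sphere and < 1 otherwise.

``l1 >= l2 >= l3`` are eigenvalues of the covariance matrix of the label's
voxel-center coordinates, computed on the raw (not square-rooted)
eigenvalues.  Surface area comes from a smoothed marching-cubes isosurface;
an unsmoothed binary isosurface overestimates a sphere's area by several
percent, which would bias sphericity downward.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from .volume import (DegenerateGeometryError, VoxelVolume, resolve_axis)

logger = logging.getLogger(__name__)

_DEGENERATE_RTOL = 1e-12
#: Tolerance on sphericity exceeding 1 before the mesh is declared broken.
SPHERICITY_TOLERANCE = 0.05


class InternalConsistencyError(RuntimeError):
    """Raised when computed metrics violate a geometric bound (broken mesh)."""


@dataclass(frozen=True)
class EigenTriple:
    """Sorted eigenvalues (mm^2) of the voxel-coordinate covariance matrix."""

    l1: float
    l2: float
    l3: float
    degenerate: bool = False

    def __post_init__(self):
        if not (np.isfinite([self.l1, self.l2, self.l3]).all()):
            raise ValueError("eigenvalues must be finite")
        if not (self.l1 >= self.l2 >= self.l3 >= -1e-12):
            raise ValueError(
                f"eigenvalues must satisfy l1 >= l2 >= l3 >= 0, "
                f"got {(self.l1, self.l2, self.l3)}")

    @property
    def anisotropy(self) -> float:
        return 1.0 - self.l3 / self.l1

    @property
    def flatness(self) -> float:
        return self.l3 / self.l2

    @property
    def elongation(self) -> float:
        return self.l2 / self.l1


@dataclass(frozen=True)
class TriangleMesh:
    """Closed triangle mesh in physical coordinates (mm)."""

    vertices: np.ndarray
    faces: np.ndarray

    @property
    def area(self) -> float:
        return float(trimesh.Trimesh(self.vertices, self.faces, process=False).area)

    @property
    def is_closed(self) -> bool:
        return bool(trimesh.Trimesh(self.vertices, self.faces, process=False).is_watertight)


@dataclass(frozen=True)
class LensShapeMetrics:
    """The four shape scores plus absolute size measures for one lens."""

    anisotropy: float
    flatness: float
    elongation: float
    sphericity: float
    volume_mm3: float
    surface_area_mm2: float


def covariance_matrix(volume: VoxelVolume, label: int) -> np.ndarray:
    """Population covariance (mm^2) of the label's voxel-center coordinates."""
    points = volume.voxel_centers(label)
    if points.shape[0] < 4:
        raise DegenerateGeometryError(
            f"label {label} has only {points.shape[0]} voxels; need >= 4")
    centered = points - points.mean(axis=0)
    return centered.T @ centered / points.shape[0]


def covariance_eigenvalues(volume: VoxelVolume, label: int) -> EigenTriple:
    """Eigenvalues of the voxel-coordinate covariance, sorted descending.

    Each foreground voxel center is an equally weighted point in physical
    coordinates, so the result is invariant to translation and (up to
    re-sorting) to permutation of axes.  Collinear or coplanar labels yield
    ``l3 == 0`` with ``degenerate=True`` rather than silently propagating a
    division by zero downstream.
    """
    cov = covariance_matrix(volume, label)
    eigvals = np.linalg.eigvalsh(cov)[::-1]
    eigvals = np.clip(eigvals, 0.0, None)
    degenerate = bool(eigvals[2] <= _DEGENERATE_RTOL * max(eigvals[0], 1e-300))
    return EigenTriple(*map(float, eigvals), degenerate=degenerate)


def _largest_component(mask: np.ndarray, label: int) -> np.ndarray:
    """Keep the largest 26-connected component, warning if there are several."""
    structure = np.ones((3, 3, 3), dtype=bool)
    labelled, n = ndimage.label(mask, structure=structure)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labelled, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        logger.warning(
            "label %d has %d connected components; keeping the largest "
            "(%d of %d voxels)", label, n, int(sizes.max()), int(sizes.sum()))
        return labelled == keep
    return mask


def extract_surface_mesh(volume: VoxelVolume, label: int,
                         smoothing: int = 20) -> TriangleMesh:
    """Closed isosurface mesh of a label at level 0.5, in mm.

    The mask is padded by one voxel before marching cubes so labels touching
    the grid boundary still yield a closed (watertight) surface.  ``smoothing``
    is the iteration count of a Taubin (shrinkage-compensated Laplacian)
    filter applied before area measurement; 0 disables smoothing.
    """
    if smoothing < 0:
        raise ValueError("smoothing must be a non-negative integer")
    mask = _largest_component(volume.mask(label), label)
    padded = np.pad(mask, 1).astype(np.float32)
    spacing = np.asarray(volume.spacing)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    # marching_cubes places voxel *indices* at integer coordinates; shift to
    # the package convention (centers at (index + 0.5) * spacing) and undo
    # the one-voxel pad.
    verts = verts + spacing * (0.5 - 1.0)
    mesh = trimesh.Trimesh(verts, faces, process=False)
    if smoothing > 0:
        trimesh.smoothing.filter_taubin(mesh, lamb=0.5, nu=0.53, iterations=smoothing)
    if not mesh.is_watertight:
        raise InternalConsistencyError(
            f"isosurface of label {label} is not closed")
    return TriangleMesh(vertices=np.asarray(mesh.vertices),
                        faces=np.asarray(mesh.faces))


def label_volume_mm3(volume: VoxelVolume, label: int) -> float:
    """Foreground voxel count times the physical voxel volume."""
    return float(volume.mask(label).sum()) * volume.voxel_volume_mm3


def sphericity_from(volume_mm3: float, surface_area_mm2: float) -> float:
    """Area of the equal-volume sphere divided by the measured area."""
    return float(np.pi ** (1 / 3) * (6.0 * volume_mm3) ** (2 / 3) / surface_area_mm2)


def compute_shape_metrics(volume: VoxelVolume, label: int,
                          mesh_smoothing: int = 20) -> LensShapeMetrics:
    """All four shape metrics plus volume and surface area for one label.

    Raises :class:`~lenshape.volume.DegenerateGeometryError` for labels whose
    voxels are collinear/coplanar and :class:`InternalConsistencyError` if
    the measured sphericity exceeds 1 by more than the mesh tolerance.
    """
    eig = covariance_eigenvalues(volume, label)
    if eig.degenerate:
        raise DegenerateGeometryError(
            f"label {label} is collinear or coplanar (l3 = 0); "
            "shape ratios are undefined")
    vol = label_volume_mm3(volume, label)
    mesh = extract_surface_mesh(volume, label, smoothing=mesh_smoothing)
    area = mesh.area
    sph = sphericity_from(vol, area)
    if sph > 1.0 + SPHERICITY_TOLERANCE:
        raise InternalConsistencyError(
            f"sphericity {sph:.4f} exceeds 1 + {SPHERICITY_TOLERANCE}; "
            "surface mesh is inconsistent with the voxel volume")
    return LensShapeMetrics(
        anisotropy=eig.anisotropy,
        flatness=eig.flatness,
        elongation=eig.elongation,
        sphericity=sph,
        volume_mm3=vol,
        surface_area_mm2=area,
    )


def transverse_diameter(volume: VoxelVolume, label: int,
                        axis: int | str = "naso-temporal") -> float:
    """Maximum caliper extent (mm) of a label along an anatomical axis.

    This is the automated analogue of placing a plane through the rendered
    eye so that it yields the maximum transverse diameter: the maximum
    extent of the label parallel to the named axis over all planes.
    """
    ax = resolve_axis(axis)
    idx = np.argwhere(volume.mask(label))[:, ax]
    return float((idx.max() - idx.min() + 1) * volume.spacing[ax])


def mean_diameter(volume: VoxelVolume, labels, axis: int | str = "naso-temporal") -> float:
    """Average transverse diameter over several labels (e.g. the two eyes)."""
    values = [transverse_diameter(volume, lab, axis) for lab in labels]
    return float(np.mean(values))
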