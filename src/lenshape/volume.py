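"""Segmented label volumes with physical voxel spacing.

The anatomical axis convention is fixed throughout the package:

* axis 0 — anterior–posterior (the optical axis),
* axis 1 — dorso-ventral,
* axis 2 — naso-temporal (the transverse axis along which eye and lens
  diameters are measured).

Voxel centers sit at ``(index + 0.5) * spacing`` in millimetres.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _nrrd

logger = logging.getLogger(__name__)

#: Anatomical axis names mapped onto grid axes.
AXIS_NAMES = {
    "anterior-posterior": 0,
    "dorso-ventral": 1,
    "naso-temporal": 2,
}


class VolumeFormatError(ValueError):
    """Raised when an input file cannot be read as a 3D label stack."""


class MissingLabelError(KeyError):
    """Raised when a requested label has no voxels in the volume."""


class DegenerateGeometryError(ValueError):
    """Raised when a label's voxels span fewer than three dimensions."""


@dataclass(frozen=True)
class VoxelVolume:
    """A 3D integer label grid with physical voxel spacing (mm).

    Label 0 is background.  ``spacing`` gives the voxel edge length along
    each of the three anatomical axes.
    """

    grid: np.ndarray
    spacing: tuple[float, float, float]
    axis_order: tuple[str, str, str] = field(
        default=("anterior-posterior", "dorso-ventral", "naso-temporal"))

    def __post_init__(self):
        grid = np.asarray(self.grid)
        if grid.ndim != 3:
            raise VolumeFormatError(f"expected 3D grid, got {grid.ndim}D")
        if not np.issubdtype(grid.dtype, np.integer):
            raise VolumeFormatError(f"labels must be integers, got {grid.dtype}")
        if grid.min() < 0:
            raise VolumeFormatError("labels must be non-negative")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "spacing", spacing)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def labels(self) -> np.ndarray:
        """Foreground labels present in the grid, sorted."""
        values = np.unique(self.grid)
        return values[values > 0]

    def mask(self, label: int) -> np.ndarray:
        """Boolean mask of one label; raises :class:`MissingLabelError` if absent."""
        mask = self.grid == label
        if not mask.any():
            raise MissingLabelError(f"label {label} not present in volume")
        return mask

    def voxel_centers(self, label: int) -> np.ndarray:
        """Physical coordinates (mm) of the centers of the label's voxels."""
        idx = np.argwhere(self.mask(label))
        return (idx + 0.5) * np.asarray(self.spacing)


def load_label_volume(path: str | Path,
                      spacing: tuple[float, float, float] | None = None) -> VoxelVolume:
    """Load a segmented label volume from a TIFF stack or NRRD file.

    Parameters
    ----------
    path
        Multi-page TIFF (page axis = axis 0) or NRRD file.
    spacing
        Per-axis voxel edge length in mm.  For NRRD files with an embedded
        spacing, the header value takes precedence and a warning is logged
        if the argument disagrees.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    header_spacing = None
    if suffix == ".nrrd":
        try:
            grid, header = _nrrd.read(path)
        except ValueError as exc:
            raise VolumeFormatError(str(exc)) from exc
        header_spacing = header.get("spacings")
    else:
        import tifffile
        try:
            grid = tifffile.imread(path)
        except Exception as exc:  # tifffile raises several unrelated types
            raise VolumeFormatError(f"cannot read {path} as TIFF: {exc}") from exc
    grid = np.asarray(grid)
    if grid.ndim != 3:
        raise VolumeFormatError(
            f"{path} has {grid.ndim} dimensions; expected a 3D label stack")
    if not np.issubdtype(grid.dtype, np.integer):
        if np.allclose(grid, np.round(grid)):
            grid = grid.astype(np.int32)
        else:
            raise VolumeFormatError(f"{path} does not contain integer labels")

    if header_spacing is not None:
        if spacing is not None and not np.allclose(header_spacing, spacing):
            logger.warning(
                "NRRD header spacing %s overrides argument %s for %s",
                header_spacing, tuple(spacing), path)
        spacing = tuple(header_spacing)
    if spacing is None:
        raise ValueError(f"no spacing supplied and none embedded in {path}")
    return VoxelVolume(grid=grid, spacing=tuple(spacing))


def resolve_axis(axis: int | str) -> int:
    """Map an anatomical axis name (or grid axis index) to a grid axis."""
    if isinstance(axis, str):
        key = axis.strip().lower().replace("_", "-").replace(" ", "-")
        if key not in AXIS_NAMES:
            raise ValueError(
                f"unknown axis {axis!r}; expected one of {sorted(AXIS_NAMES)}")
        return AXIS_NAMES[key]
    axis = int(axis)
    if axis not in (0, 1, 2):
        raise ValueError(f"grid axis must be 0, 1 or 2, got {axis}")
    return axis
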