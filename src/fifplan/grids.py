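"""Axis-aligned voxel grids and structure masks.

The whole planner runs on one voxel substrate: a 3D scalar field
(:class:`ImageGrid`, holding density in g/cm^3 or dose in Gy) plus named
boolean masks co-registered to it (:class:`StructureMask`).  The coordinate
convention is fixed once and used everywhere:

* axes: x = patient right -> left, y = anterior -> posterior,
  z = inferior -> superior;
* voxel indices are 0-based; world coordinates refer to voxel centers;
* ``origin`` is the world position (mm) of the center of voxel (0, 0, 0).

Grids and masks persist as single-file NIfTI (.nii) through nibabel, with the
spacing/origin carried in the affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np


class GridAlignmentError(ValueError):
    """Raised when a mask or dose grid does not share its reference grid's frame."""


@dataclass
class ImageGrid:
    """A 3D scalar field on a regular axis-aligned grid.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Scalar samples at voxel centers (density in g/cm^3 or dose in Gy).
    spacing : tuple of float
        Voxel spacing (dx, dy, dz) in mm; all positive.
    origin : tuple of float
        World coordinates (mm) of the center of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacings must be three positive numbers, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_cm3(self) -> float:
        """Volume of one voxel in cm^3 (spacings are mm)."""
        dx, dy, dz = self.spacing
        return dx * dy * dz / 1000.0

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centers along each axis (three 1D arrays, mm)."""
        return tuple(
            self.origin[i] + self.spacing[i] * np.arange(self.shape[i])
            for i in range(3)
        )

    def same_frame(self, other: "ImageGrid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def like(self, values: np.ndarray) -> "ImageGrid":
        """New grid with the same frame but different values."""
        if values.shape != self.shape:
            raise GridAlignmentError(
                f"values shape {values.shape} != grid shape {self.shape}"
            )
        return ImageGrid(values, self.spacing, self.origin)


@dataclass
class StructureMask:
    """A named boolean region aligned to a reference :class:`ImageGrid`."""

    name: str
    mask: np.ndarray
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={self.mask.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    def volume_cm3(self) -> float:
        dx, dy, dz = self.spacing
        return float(self.mask.sum()) * dx * dy * dz / 1000.0

    def check_aligned(self, grid: ImageGrid) -> None:
        if self.shape != grid.shape:
            raise GridAlignmentError(
                f"mask {self.name!r} shape {self.shape} != grid shape {grid.shape}"
            )
        if not (
            np.allclose(self.spacing, grid.spacing)
            and np.allclose(self.origin, grid.origin)
        ):
            raise GridAlignmentError(
                f"mask {self.name!r} world frame differs from reference grid"
            )


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = origin
    return aff


def write_grid(grid: ImageGrid, path: str) -> None:
    """Persist a grid as single-file NIfTI; values stored as float32."""
    img = nib.Nifti1Image(
        grid.values.astype(np.float32), _affine(grid.spacing, grid.origin)
    )
    nib.save(img, path)


def read_grid(path: str) -> ImageGrid:
    img = nib.load(path)
    aff = img.affine
    spacing = tuple(float(aff[i, i]) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    return ImageGrid(np.asarray(img.dataobj, dtype=np.float64), spacing, origin)


def write_mask(mask: StructureMask, path: str) -> None:
    img = nib.Nifti1Image(
        mask.mask.astype(np.uint8), _affine(mask.spacing, mask.origin)
    )
    nib.save(img, path)


def read_mask(path: str, name: str, reference: ImageGrid | None = None) -> StructureMask:
    """Read a mask; if ``reference`` is given, verify alignment with it."""
    img = nib.load(path)
    aff = img.affine
    mask = StructureMask(
        name=name,
        mask=np.asarray(img.dataobj) > 0,
        spacing=tuple(float(aff[i, i]) for i in range(3)),
        origin=tuple(float(aff[i, 3]) for i in range(3)),
    )
    if reference is not None:
        mask.check_aligned(reference)
    return mask
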