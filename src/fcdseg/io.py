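"""NIfTI input/output for 3D volumes and binary lesion masks.

The unit of all image processing in this package is :class:`Volume`: a 3D
intensity array together with its 4x4 voxel-to-world affine (mm) and the
per-axis voxel spacing derived from it. :class:`LesionMask` is the paired
binary ground-truth/prediction container; its voxels are exactly 0 or 1 and
its grid must match the reference volume's.

Geometry survives write/read round trips: affines and pixdim to well below
1e-6, voxel data bitwise for integer dtypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .exceptions import DimensionalityError, GeometryError

__all__ = ["Volume", "LesionMask", "read_volume", "read_mask", "write_volume"]


def _spacing_from_affine(affine: np.ndarray) -> np.ndarray:
    """Per-axis voxel size (mm): Euclidean norms of the affine's columns."""
    return np.sqrt((np.asarray(affine, dtype=float)[:3, :3] ** 2).sum(axis=0))


def _validate_grid(data: np.ndarray, what: str) -> np.ndarray:
    data = np.asarray(data)
    if data.ndim != 3:
        raise DimensionalityError(
            f"{what} must be 3-D, got a {data.ndim}-D array of shape {data.shape}"
        )
    if min(data.shape) < 1:
        raise DimensionalityError(f"{what} has an empty axis: shape {data.shape}")
    return data


@dataclass
class Volume:
    """A 3D intensity image with world geometry.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel intensities in arbitrary scanner units.
    affine : ndarray, shape (4, 4)
        Voxel-index to world-mm transform (NIfTI convention, 0-based indices).
    spacing : ndarray, optional
        Per-axis voxel size in mm. Derived from the affine when omitted;
        when given it must agree with the affine's column norms to 1e-3 mm.
    axial_axis : int
        Which array axis runs inferior-superior (the axial slice axis).
        The third axis by default.
    """

    data: np.ndarray
    affine: np.ndarray
    spacing: np.ndarray | None = None
    axial_axis: int = 2

    def __post_init__(self) -> None:
        self.data = _validate_grid(self.data, type(self).__name__)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise GeometryError(f"affine must be 4x4, got {self.affine.shape}")
        derived = _spacing_from_affine(self.affine)
        if self.spacing is None:
            self.spacing = derived
        else:
            self.spacing = np.asarray(self.spacing, dtype=float)
            if self.spacing.shape != (3,):
                raise GeometryError("spacing must have three entries")
            if np.any(np.abs(self.spacing - derived) > 1e-3):
                raise GeometryError(
                    f"spacing {self.spacing} inconsistent with affine column "
                    f"norms {derived} (tolerance 1e-3 mm)"
                )
        if np.any(self.spacing <= 0):
            raise GeometryError(f"spacing must be strictly positive, got {self.spacing}")
        if self.axial_axis not in (0, 1, 2):
            raise GeometryError(f"axial_axis must be 0, 1 or 2, got {self.axial_axis}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)

    @property
    def n_slices(self) -> int:
        """Number of axial slices."""
        return self.data.shape[self.axial_axis]

    def with_data(self, data: np.ndarray) -> "Volume":
        """Same geometry, new voxel data (shape must match)."""
        if np.asarray(data).shape != self.shape:
            raise GeometryError(
                f"replacement data shape {np.asarray(data).shape} != {self.shape}"
            )
        return Volume(np.asarray(data), self.affine.copy(), self.spacing.copy(), self.axial_axis)


@dataclass
class LesionMask:
    """A voxel-aligned binary mask on the same grid as its paired Volume."""

    data: np.ndarray
    affine: np.ndarray
    spacing: np.ndarray | None = None
    axial_axis: int = 2

    def __post_init__(self) -> None:
        data = _validate_grid(self.data, type(self).__name__)
        values = np.unique(data)
        if not np.isin(values, (0, 1)).all():
            raise ValueError(
                f"mask voxels must all be 0 or 1; found values {values[:8]} "
                "(binarize first, e.g. preprocess.binarize_mask)"
            )
        self.data = data.astype(np.uint8)
        geom = Volume(self.data, affine=self.affine, spacing=self.spacing,
                      axial_axis=self.axial_axis)
        self.affine, self.spacing, self.axial_axis = geom.affine, geom.spacing, geom.axial_axis

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)

    @property
    def lesion_voxels(self) -> int:
        return int(self.data.sum())

    def check_aligned(self, reference: Volume) -> None:
        if self.shape != reference.shape:
            raise GeometryError(
                f"mask shape {self.shape} does not match reference shape {reference.shape}"
            )


def read_volume(path, axial_axis: int = 2) -> Volume:
    """Load a 3D NIfTI image.

    Values equal the on-disk values after applying the NIfTI scale
    slope/intercept; integer images without scaling keep their dtype.
    Raises ``FileNotFoundError`` for a missing file, ``DimensionalityError``
    for non-3D images, and nibabel's format errors for corrupt headers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise DimensionalityError(
            f"{path} is {len(img.shape)}-D (shape {tuple(img.shape)}); expected a 3-D image"
        )
    data = np.asanyarray(img.dataobj)  # applies scl_slope/scl_inter when set
    return Volume(data=data, affine=img.affine, axial_axis=axial_axis)


def read_mask(path, reference: Volume) -> LesionMask:
    """Load a binary lesion mask and check voxel alignment with ``reference``."""
    vol = read_volume(path, axial_axis=reference.axial_axis)
    if vol.shape != reference.shape:
        raise GeometryError(
            f"mask shape {vol.shape} does not match reference shape {reference.shape}"
        )
    return LesionMask(data=vol.data, affine=vol.affine, axial_axis=reference.axial_axis)


def write_volume(v: Volume | LesionMask, path) -> None:
    """Write a Volume or LesionMask as NIfTI (.nii or .nii.gz).

    Masks are stored as unsigned 8-bit; images keep their native dtype.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = v.data
    if isinstance(v, LesionMask):
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, v.affine)
    img.header.set_zooms(tuple(float(s) for s in v.spacing))
    nib.save(img, str(path))
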