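"""Volume I/O and grid bookkeeping.

All volumes are held in a canonical patient frame with axes pointing
left / posterior / superior (LPS) and array index order ``(x, y, z)``,
``z`` being the slice axis.  Physical positions are
``origin + index * spacing`` in mm.  NIfTI (``.nii``/``.nii.gz``) is the
interchange format; a directory holding a single DICOM series can be
read as well.  SimpleITK does the heavy lifting — its world frame is
LPS already, so a volume with an identity direction matrix is in the
canonical orientation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import SimpleITK as sitk

from .errors import CohortError, FormatError, PreconditionError, AmbiguityError

_IDENTITY = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)


@dataclass
class ImageVolume:
    """A 3D scalar field (MR intensities or HU) with grid metadata.

    Attributes
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Scalar samples; all values must be finite.
    spacing : tuple of float
        Voxel size in mm along (x, y, z); strictly positive.
    origin : tuple of float
        Physical position (mm, LPS) of voxel (0, 0, 0).
    direction : tuple of 9 floats
        Row-major axis-direction cosine matrix; identity means the
        canonical LPS orientation.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, ...] = _IDENTITY

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise PreconditionError("voxels must be a 3D array with each dimension >= 1")
        if not np.all(np.isfinite(self.voxels)):
            raise PreconditionError("voxels must all be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise PreconditionError("spacing must be three strictly positive values")
        self.origin = tuple(float(o) for o in self.origin)
        self.direction = tuple(float(d) for d in self.direction)

    # -- grid helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def grid(self) -> tuple:
        """Hashable grid descriptor used for consistency checks."""
        return (self.shape, self.spacing, self.origin, self.direction)

    def like(self, voxels: np.ndarray) -> "ImageVolume":
        """A new volume with the same grid and the given voxel data."""
        return ImageVolume(np.asarray(voxels), self.spacing, self.origin, self.direction)

    def coords_mm(self):
        """Physical coordinates (mm) of all voxel centers, one array per axis."""
        axes = [self.origin[i] + self.spacing[i] * np.arange(self.shape[i]) for i in range(3)]
        return np.meshgrid(*axes, indexing="ij")


@dataclass
class BinaryMask:
    """A boolean field sharing the grid of a reference :class:`ImageVolume`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, ...] = _IDENTITY

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise PreconditionError("mask must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.direction = tuple(float(d) for d in self.direction)

    @classmethod
    def from_volume(cls, ref, voxels: np.ndarray) -> "BinaryMask":
        if np.asarray(voxels).shape != ref.shape:
            raise PreconditionError("mask shape does not match reference volume")
        return cls(voxels, ref.spacing, ref.origin, ref.direction)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def grid(self) -> tuple:
        return (self.shape, self.spacing, self.origin, self.direction)

    def count(self) -> int:
        return int(self.voxels.sum())

    def replace_voxels(self, voxels: np.ndarray) -> "BinaryMask":
        return replace(self, voxels=np.asarray(voxels).astype(bool))


# ---------------------------------------------------------------------
# SimpleITK conversion (sitk arrays are indexed (z, y, x))
# ---------------------------------------------------------------------

def to_sitk(volume, dtype=np.float32) -> sitk.Image:
    arr = np.ascontiguousarray(volume.voxels.transpose(2, 1, 0).astype(dtype))
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(volume.spacing)
    img.SetOrigin(volume.origin)
    img.SetDirection(volume.direction)
    return img


def from_sitk(img: sitk.Image) -> ImageVolume:
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return ImageVolume(arr, img.GetSpacing(), img.GetOrigin(), img.GetDirection())


def _canonicalize(img: sitk.Image) -> sitk.Image:
    """Reorient to the canonical LPS frame (identity direction matrix)."""
    if img.GetDimension() != 3:
        raise FormatError(f"expected a 3D volume, got {img.GetDimension()}D")
    if tuple(round(d, 6) for d in img.GetDirection()) != _IDENTITY:
        img = sitk.DICOMOrient(img, "LPS")
    return img


# ---------------------------------------------------------------------
# Read / write
# ---------------------------------------------------------------------

def read_volume(path) -> ImageVolume:
    """Read a NIfTI file or a directory holding exactly one DICOM series.

    Volumes are reoriented to the canonical LPS frame on read; voxel
    intensities are returned unmodified.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FormatError(f"no such file or directory: {path}")
    if os.path.isdir(path):
        reader = sitk.ImageSeriesReader()
        series = reader.GetGDCMSeriesIDs(path)
        if len(series) == 0:
            raise FormatError(f"no DICOM series found in {path}")
        if len(series) > 1:
            raise AmbiguityError(
                f"directory {path} contains {len(series)} DICOM series: "
                + ", ".join(series)
            )
        reader.SetFileNames(reader.GetGDCMSeriesFileNames(path, series[0]))
        try:
            img = reader.Execute()
        except RuntimeError as e:  # pragma: no cover - GDCM error text varies
            raise FormatError(f"failed to read DICOM series from {path}: {e}") from e
    else:
        try:
            img = sitk.ReadImage(path)
        except RuntimeError as e:
            raise FormatError(f"failed to read {path}: {e}") from e
    return from_sitk(_canonicalize(img))


def write_volume(volume: ImageVolume, path, dtype=np.float32) -> None:
    """Write a volume as NIfTI; lossless for 32-bit float data."""
    if not np.all(np.isfinite(volume.voxels)):
        raise PreconditionError("cannot write volume with non-finite voxels")
    try:
        sitk.WriteImage(to_sitk(volume, dtype=dtype), os.fspath(path))
    except RuntimeError as e:
        raise OSError(f"failed to write {path}: {e}") from e


def write_mask(mask: BinaryMask, path) -> None:
    """Write a mask as an unsigned 8-bit NIfTI volume (0/1)."""
    vol = ImageVolume(mask.voxels.astype(np.uint8), mask.spacing, mask.origin, mask.direction)
    write_volume(vol, path, dtype=np.uint8)


def read_mask(path) -> BinaryMask:
    vol = read_volume(path)
    return BinaryMask(vol.voxels != 0, vol.spacing, vol.origin, vol.direction)


# ---------------------------------------------------------------------
# Cohort consistency
# ---------------------------------------------------------------------

def check_cohort(inphase, fat, water, *, spacing_tol_mm: float = 1e-4,
                 origin_tol_mm: float = 1e-3) -> None:
    """Verify the three mDixon channels share one grid.

    Raises :class:`CohortError` naming the first offending field
    (shape, spacing, origin or orientation); passes silently otherwise.
    """
    vols = {"inphase": inphase, "fat": fat, "water": water}
    for name, v in vols.items():
        if v is None:
            raise PreconditionError(f"{name} volume is missing")
    ref_name, ref = "inphase", inphase
    for name, v in vols.items():
        if v.shape != ref.shape:
            raise CohortError(f"shape mismatch: {ref_name}={ref.shape}, {name}={v.shape}")
        if any(abs(a - b) > spacing_tol_mm for a, b in zip(v.spacing, ref.spacing)):
            raise CohortError(
                f"spacing mismatch: {ref_name}={ref.spacing}, {name}={v.spacing}")
        if any(abs(a - b) > origin_tol_mm for a, b in zip(v.origin, ref.origin)):
            raise CohortError(f"origin mismatch: {ref_name}={ref.origin}, {name}={v.origin}")
        if any(abs(a - b) > 1e-6 for a, b in zip(v.direction, ref.direction)):
            raise CohortError(
                f"orientation mismatch: {ref_name}={ref.direction}, {name}={v.direction}")
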