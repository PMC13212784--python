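"""NIfTI input/output, canonical orientation, and isotropic resampling.

The pipeline's universal carrier is :class:`CTVolume`: a 3D float32 array of
Hounsfield units plus grid metadata (spacing, origin, direction cosines).
Arrays are indexed ``[i, j, k]`` with axis 0 the left-right (sagittal) axis;
inputs are reoriented to the closest RAS frame at load so hemisphere splitting
always happens along a known axis.  Binary masks carry the same grid metadata
and are stored as unsigned 8-bit on disk.

All geometric quantities (spacing, origin, displacements) are in millimetres.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, replace

import nibabel as nib
import numpy as np
import SimpleITK as sitk

from .errors import VolumeFormatError, VolumeIOError

_IDENTITY_DIRECTION = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)

#: minimum grid dimension accepted after resampling; smaller volumes cannot
#: hold even a single pooling kernel and are rejected as degenerate.
MIN_DIM = 8


def _as_tuple3(x) -> tuple[float, float, float]:
    t = tuple(float(v) for v in x)
    if len(t) != 3:
        raise ValueError(f"expected a 3-tuple, got {x!r}")
    return t


@dataclass
class CTVolume:
    """A 3D scalar HU grid with world-space metadata.

    Parameters
    ----------
    values
        ``(nx, ny, nz)`` array; stored as float32 regardless of input dtype.
    spacing
        Voxel edge lengths ``(sx, sy, sz)`` in mm, strictly positive.
    origin
        World coordinates (mm) of the centre of voxel ``(0, 0, 0)``.
    direction
        Row-major 3x3 direction cosine matrix (NIfTI/ITK convention).
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, ...] = _IDENTITY_DIRECTION

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise VolumeFormatError(f"expected a 3D scalar volume, got ndim={arr.ndim}")
        if arr.dtype != np.float32:
            arr = arr.astype(np.float32)
        if not np.isfinite(arr).all():
            raise VolumeFormatError("volume contains NaN or Inf voxel values")
        self.values = arr
        self.spacing = _as_tuple3(self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise VolumeFormatError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = _as_tuple3(self.origin)
        self.direction = tuple(float(v) for v in self.direction)
        if len(self.direction) != 9:
            raise VolumeFormatError("direction must have 9 entries (row-major 3x3)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other: "CTVolume | BinaryMask", tol: float = 1e-4) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.direction, other.direction, atol=tol)
        )

    def with_values(self, values: np.ndarray) -> "CTVolume":
        return replace(self, values=values)

    # -- SimpleITK interop -------------------------------------------------
    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.values.transpose(2, 1, 0)))
        img.SetSpacing(self.spacing)
        img.SetOrigin(self.origin)
        img.SetDirection(self.direction)
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "CTVolume":
        arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return cls(
            values=np.ascontiguousarray(arr, dtype=np.float32),
            spacing=img.GetSpacing(),
            origin=img.GetOrigin(),
            direction=img.GetDirection(),
        )


@dataclass
class BinaryMask:
    """A {0,1} voxel mask sharing its grid metadata with a companion volume."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, ...] = _IDENTITY_DIRECTION

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise VolumeFormatError(f"expected a 3D mask, got ndim={arr.ndim}")
        if arr.dtype == bool:
            arr = arr.astype(np.uint8)
        else:
            uniq = np.unique(arr)
            if not np.isin(uniq, (0, 1)).all():
                raise VolumeFormatError(f"mask values must be in {{0,1}}, got {uniq[:10]}")
            arr = arr.astype(np.uint8)
        self.values = arr
        self.spacing = _as_tuple3(self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise VolumeFormatError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = _as_tuple3(self.origin)
        self.direction = tuple(float(v) for v in self.direction)

    shape = CTVolume.shape
    voxel_volume_mm3 = CTVolume.voxel_volume_mm3
    same_grid = CTVolume.same_grid

    @property
    def bool_values(self) -> np.ndarray:
        return self.values.astype(bool)

    @property
    def count(self) -> int:
        return int(self.values.sum())

    @property
    def volume_ml(self) -> float:
        return self.count * self.voxel_volume_mm3 / 1000.0

    def with_values(self, values: np.ndarray) -> "BinaryMask":
        return replace(self, values=values)

    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.values.transpose(2, 1, 0)))
        img.SetSpacing(self.spacing)
        img.SetOrigin(self.origin)
        img.SetDirection(self.direction)
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "BinaryMask":
        arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return cls(
            values=(np.ascontiguousarray(arr) > 0.5).astype(np.uint8),
            spacing=img.GetSpacing(),
            origin=img.GetOrigin(),
            direction=img.GetDirection(),
        )


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------

def _load_canonical(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI file reoriented to the closest RAS frame.

    Returns the data array and the 4x4 affine.  Axis 0 of the returned array
    is the left-right world axis, which hemisphere splitting relies on.
    """
    if not os.path.exists(path):
        raise VolumeIOError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        img = nib.as_closest_canonical(img)
        data = np.asanyarray(img.dataobj)
        affine = img.affine
    except VolumeIOError:
        raise
    except Exception as exc:  # nibabel raises various types for corrupt files
        raise VolumeIOError(f"cannot read NIfTI file {path}: {exc}") from exc
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected a 3D scalar image, got shape {data.shape}")
    return np.asarray(data), np.asarray(affine, dtype=float)


def _grid_from_affine(affine: np.ndarray):
    lin = affine[:3, :3]
    spacing = np.linalg.norm(lin, axis=0)
    if np.any(spacing <= 0):
        raise VolumeFormatError(f"degenerate affine, spacing {spacing}")
    direction = (lin / spacing).T.ravel()  # row-major, columns are axis directions
    origin = affine[:3, 3]
    return tuple(spacing), tuple(origin), tuple(direction)


def read_volume(path) -> CTVolume:
    """Read a scalar NIfTI volume as a :class:`CTVolume` (HU, float32, RAS)."""
    data, affine = _load_canonical(path)
    spacing, origin, direction = _grid_from_affine(affine)
    return CTVolume(values=data.astype(np.float32), spacing=spacing, origin=origin,
                    direction=direction)


def read_mask(path) -> BinaryMask:
    """Read a binary NIfTI mask; any value > 0.5 counts as foreground."""
    data, affine = _load_canonical(path)
    spacing, origin, direction = _grid_from_affine(affine)
    return BinaryMask(values=(data > 0.5).astype(np.uint8), spacing=spacing,
                      origin=origin, direction=direction)


def _affine_of(vol: CTVolume | BinaryMask) -> np.ndarray:
    aff = np.eye(4)
    dirm = np.asarray(vol.direction, dtype=float).reshape(3, 3)
    aff[:3, :3] = dirm.T * np.asarray(vol.spacing)
    aff[:3, 3] = vol.origin
    return aff


def write_volume(vol: CTVolume | BinaryMask, path) -> None:
    """Write a volume (float32) or mask (uint8) to NIfTI."""
    parent = os.path.dirname(os.path.abspath(str(path)))
    if not os.path.isdir(parent) or not os.access(parent, os.W_OK):
        raise VolumeIOError(f"cannot write to {path}: directory not writable")
    dtype = np.uint8 if isinstance(vol, BinaryMask) else np.float32
    img = nib.Nifti1Image(vol.values.astype(dtype), _affine_of(vol))
    img.header.set_data_dtype(dtype)
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise VolumeIOError(f"cannot write NIfTI file {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def _target_size(shape, spacing, target: float) -> tuple[int, int, int]:
    # keep every output voxel centre inside the input domain so that linear
    # interpolation never extrapolates (a constant volume stays constant)
    return tuple(int(np.floor((n - 1) * s / target)) + 1 for n, s in zip(shape, spacing))


def resample_isotropic(vol, target_spacing: float = 1.0, interpolation: str = "linear"):
    """Resample onto an isotropic ``target_spacing`` grid.

    Linear interpolation for HU volumes, nearest-neighbour for masks (required:
    nearest keeps mask values in {0,1}).  The output grid shares the input
    origin and direction; physical extent is preserved within one voxel per
    axis.  Returns the same type as the input.
    """
    if target_spacing <= 0:
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    is_mask = isinstance(vol, BinaryMask)
    if is_mask and interpolation != "nearest":
        raise ValueError("binary masks must be resampled with nearest interpolation")

    size = _target_size(vol.shape, vol.spacing, target_spacing)
    if any(n < MIN_DIM for n in size):
        raise VolumeFormatError(
            f"volume degenerate after resampling to {target_spacing} mm: size {size}")

    img = vol.to_sitk()
    res = sitk.ResampleImageFilter()
    res.SetSize(size)
    res.SetOutputSpacing((target_spacing,) * 3)
    res.SetOutputOrigin(vol.origin)
    res.SetOutputDirection(vol.direction)
    res.SetTransform(sitk.Transform())
    res.SetInterpolator(sitk.sitkNearestNeighbor if interpolation == "nearest"
                        else sitk.sitkLinear)
    res.SetDefaultPixelValue(0.0)
    out = res.Execute(img)
    return BinaryMask.from_sitk(out) if is_mask else CTVolume.from_sitk(out)
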