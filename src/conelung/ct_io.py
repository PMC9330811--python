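"""Reading, writing and reorientation of microCT volumes and binary masks.

Conventions
-----------
Arrays are indexed ``(z, y, x)`` with axis 0 the axial (cranio-caudal)
direction, axis 1 the coronal (dorso-ventral) direction and axis 2 the
sagittal (left-right) direction.  Voxel indices are 0-based; the physical
coordinate of a voxel center is ``index * spacing`` in millimetres, and all
distances and volumes are reported in mm / mm³.

Grey values straight off the scanner are non-negative integers
(``units="raw_grey"``); after Hounsfield calibration voxels are floating
point and may be negative (``units="HU"``, air = −1000, water = 0).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

__all__ = [
    "CTVolume",
    "VOIMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "reorient",
    "reorient_mask",
    "rotation_from_euler",
    "rotate_points",
]

#: axis labels of the standardized analysis frame
STANDARD_ORIENTATION = ("axial", "coronal", "sagittal")

_FORMAT_EXTENSIONS = {
    "nifti": (".nii", ".nii.gz"),
    "metaimage": (".mhd", ".mha"),
}


@dataclass
class CTVolume:
    """A 3-D scalar grid with voxel spacing and axis-orientation labels.

    Parameters
    ----------
    data :
        3-D array of grey values or Hounsfield units.
    spacing :
        Per-axis voxel size in mm, ordered like the array axes ``(z, y, x)``.
    units :
        ``"raw_grey"`` (non-negative integer scanner output) or ``"HU"``.
    orientation :
        Axis labels; defaults to the standardized analysis frame.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    units: str = "raw_grey"
    orientation: tuple[str, str, str] = STANDARD_ORIENTATION

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume must be 3-D")
        if any(s < 2 for s in self.data.shape):
            raise ValueError("each axis must span at least 2 voxels")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive values (mm)")
        if self.units not in ("raw_grey", "HU"):
            raise ValueError(f"unknown units {self.units!r}")
        if self.units == "raw_grey":
            if not np.issubdtype(self.data.dtype, np.integer):
                raise ValueError("raw_grey volumes must hold integer data")
            if self.data.size and self.data.min() < 0:
                raise ValueError("raw_grey volumes must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of a single voxel in mm³."""
        return float(np.prod(self.spacing))

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical coordinate of the last voxel center along each axis."""
        return tuple((n - 1) * s for n, s in zip(self.shape, self.spacing))


@dataclass
class VOIMask:
    """Binary volume-of-interest mask on the grid of a :class:`CTVolume`."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError("mask must be 3-D")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask values must be 0/1")
            arr = arr.astype(bool)
        self.data = arr
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive values (mm)")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def matches_grid(self, vol: "CTVolume") -> bool:
        return self.data.shape == vol.shape and np.allclose(self.spacing, vol.spacing)


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in _FORMAT_EXTENSIONS:
            raise ValueError(f"unknown format {fmt!r}")
        return fmt
    lower = str(path).lower()
    for name, exts in _FORMAT_EXTENSIONS.items():
        if lower.endswith(exts):
            return name
    raise ValueError(f"cannot infer image format from {path!r}")


def read_volume(path: str, format: str | None = None, units: str | None = None) -> CTVolume:
    """Read a NIfTI-1 or MetaImage volume into the analysis frame.

    Spacing is taken from the header.  Unless ``units`` is given, a volume
    stored as floating point or containing negative values is tagged ``HU``,
    otherwise ``raw_grey`` — scanners emit unsigned grey values and only
    Hounsfield-calibrated data go negative.
    """
    _infer_format(path, format)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ValueError("volume must be 3-D")
    data = sitk.GetArrayFromImage(img)  # (z, y, x)
    spacing = tuple(float(s) for s in reversed(img.GetSpacing()))
    if any(s <= 0 for s in spacing):
        raise ValueError("non-positive voxel spacing in header")
    if units is None:
        if np.issubdtype(data.dtype, np.floating) or (data.size and data.min() < 0):
            units = "HU"
        else:
            units = "raw_grey"
    return CTVolume(data=data, spacing=spacing, units=units)


def write_volume(vol: CTVolume, path: str, format: str | None = None) -> str:
    """Write a volume as NIfTI-1 or MetaImage; round-trips data and spacing.

    HU volumes are stored as 32-bit float so negative values (air = −1000)
    survive unclipped; integer grey data keep their dtype.
    """
    _infer_format(path, format)
    data = vol.data
    if vol.units == "HU" and not np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    img = sitk.GetImageFromArray(data)
    img.SetSpacing(tuple(reversed(vol.spacing)))
    sitk.WriteImage(img, str(path))
    return str(path)


def read_mask(path: str, format: str | None = None) -> VOIMask:
    """Read a binary mask stored as an 8-bit NIfTI/MetaImage."""
    vol = read_volume(path, format=format, units="raw_grey")
    return VOIMask(data=vol.data, spacing=vol.spacing)


def write_mask(mask: VOIMask, path: str, format: str | None = None) -> str:
    img = sitk.GetImageFromArray(mask.data.astype(np.uint8))
    img.SetSpacing(tuple(reversed(mask.spacing)))
    _infer_format(path, format)
    sitk.WriteImage(img, str(path))
    return str(path)


# ---------------------------------------------------------------------------
# rigid reorientation


def rotation_from_euler(yaw: float = 0.0, pitch: float = 0.0, roll: float = 0.0) -> np.ndarray:
    """Rotation matrix from Euler angles in degrees.

    ``yaw`` rotates about the axial axis (axis 0, in-plane axial rotation),
    ``pitch`` about the coronal axis (axis 1) and ``roll`` about the
    sagittal axis (axis 2); they are composed in that order.
    """

    def _axis_rot(angle_deg: float, axis: int) -> np.ndarray:
        a = np.deg2rad(angle_deg)
        c, s = np.cos(a), np.sin(a)
        i, j = [k for k in range(3) if k != axis]
        R = np.eye(3)
        R[i, i] = c
        R[j, j] = c
        R[i, j] = -s
        R[j, i] = s
        return R

    return _axis_rot(roll, 2) @ _axis_rot(pitch, 1) @ _axis_rot(yaw, 0)


def _check_rotation(rotation: np.ndarray) -> np.ndarray:
    R = np.asarray(rotation, dtype=float)
    if R.shape != (3, 3):
        raise ValueError("rotation must be a 3x3 matrix")
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
        raise ValueError("rotation matrix not orthonormal within tolerance 1e-6")
    if not np.isclose(np.linalg.det(R), 1.0, atol=1e-6):
        raise ValueError("rotation must be proper (determinant +1)")
    return R


def _is_signed_permutation(R: np.ndarray) -> bool:
    A = np.abs(R)
    return bool(
        np.allclose(A[A > 0.5], 1.0, atol=1e-9)
        and np.allclose(A[A <= 0.5], 0.0, atol=1e-9)
        and np.all(A.sum(axis=0).round() == 1)
        and np.all(A.sum(axis=1).round() == 1)
    )


def _resample_rotated(data: np.ndarray, R: np.ndarray, order: int, cval: float) -> np.ndarray:
    """Rotate array content by ``R`` about the grid center.

    Signed-permutation matrices (multiples of 90°) map lattice onto lattice
    and are applied voxel-exactly; anything else is resampled with
    ``scipy.ndimage.affine_transform`` at the requested interpolation order.
    """
    in_shape = np.array(data.shape, dtype=float)
    signed_perm = _is_signed_permutation(R)
    if signed_perm:
        Rr = np.round(R)
        out_shape = (np.abs(Rr) @ in_shape).astype(int)
    else:
        Rr = R
        out_shape = data.shape
    c_in = (in_shape - 1) / 2.0
    c_out = (np.array(out_shape, dtype=float) - 1) / 2.0
    # inverse map: input index = R^T @ (output index - c_out) + c_in
    matrix = Rr.T
    offset = c_in - matrix @ c_out
    return ndimage.affine_transform(
        data,
        matrix,
        offset=offset,
        output_shape=tuple(int(n) for n in out_shape),
        order=0 if signed_perm else order,
        cval=cval,
        prefilter=False,
    )


def reorient(vol: CTVolume, rotation: np.ndarray, fill: float | None = None) -> CTVolume:
    """Rigidly rotate a volume about its center onto a same-spacing grid.

    Axis-aligned 90°/180° rotations permute voxels exactly.  Off-axis
    rotations are resampled trilinearly and require isotropic spacing (a
    rotation mixing anisotropic axes would shear physical space).
    ``fill`` defaults to the data minimum, i.e. background air.
    """
    R = _check_rotation(rotation)
    signed_perm = _is_signed_permutation(R)
    if not signed_perm and not np.allclose(vol.spacing, vol.spacing[0]):
        raise ValueError("off-axis reorientation requires isotropic spacing")
    cval = float(vol.data.min()) if fill is None else float(fill)
    data = vol.data if signed_perm else vol.data.astype(np.float32)
    out = _resample_rotated(data, R, order=1, cval=cval)
    if signed_perm:
        spacing = tuple((np.abs(np.round(R)) @ np.array(vol.spacing)).tolist())
        labels = tuple(
            vol.orientation[int(np.argmax(np.abs(np.round(R))[i]))] for i in range(3)
        )
    else:
        spacing = vol.spacing
        labels = vol.orientation
    units = vol.units
    if units == "raw_grey" and not np.issubdtype(out.dtype, np.integer):
        out = np.rint(out).clip(min=0).astype(vol.data.dtype)
    return CTVolume(data=out, spacing=spacing, units=units, orientation=labels)


def reorient_mask(mask: VOIMask, rotation: np.ndarray) -> VOIMask:
    """Rotate a binary mask with nearest-neighbour resampling (stays binary)."""
    R = _check_rotation(rotation)
    out = _resample_rotated(mask.data.astype(np.uint8), R, order=0, cval=0)
    if _is_signed_permutation(R):
        spacing = tuple((np.abs(np.round(R)) @ np.array(mask.spacing)).tolist())
    else:
        spacing = mask.spacing
    return VOIMask(data=out.astype(bool), spacing=spacing)


def rotate_points(points: np.ndarray, rotation: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Rotate physical-coordinate points (mm) with the same convention as
    :func:`reorient`: ``p' = R @ (p - center) + center``."""
    R = _check_rotation(rotation)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    c = np.asarray(center, dtype=float)
    return (pts - c) @ R.T + c
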