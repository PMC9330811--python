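"""Aerated-lung threshold segmentation and emulated manual delineation.

Two segmentations of the lung are supported:

* **Threshold segmentation** selects voxels inside an HU window — the
  reference window for aerated mouse parenchyma is −700..−300 HU (an
  alternate −700..−400 HU preset is provided).  Exterior air is removed by
  discarding connected components that touch the volume border, and specks
  below 27 voxels are dropped.  No smoothing or filtering is applied
  anywhere, so voxel intensities stay untouched.

* **Manual delineation** is emulated from closed polygon contours drawn on
  a subset of axial slices (starting at the carina).  Annotated slices are
  rasterized with even-odd fill (nested contours cut holes); slices in
  between are filled by linear interpolation of the signed distance
  transforms of the two bounding annotated slices — a standard,
  topology-tolerant stand-in for the interactive tools' undocumented
  inter-slice interpolation.  Nothing is produced outside the annotated
  extent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import draw, measure

from .ct_io import CTVolume, VOIMask

__all__ = [
    "HUWindow",
    "WINDOW_REFERENCE",
    "WINDOW_ALTERNATE",
    "SliceContourSet",
    "threshold_segment",
    "delineate_from_contours",
    "mask_volume_mm3",
    "contours_from_mask",
]

#: minimum connected-component size kept by the threshold segmentation
MIN_COMPONENT_VOXELS = 27


@dataclass(frozen=True)
class HUWindow:
    """Inclusive HU intensity window ``[low, high]``."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("window requires low < high")

    @classmethod
    def parse(cls, text: str) -> "HUWindow":
        """Parse ``"-700:-300"`` style window strings."""
        low, high = (float(v) for v in text.split(":"))
        return cls(low, high)


WINDOW_REFERENCE = HUWindow(-700.0, -300.0)
WINDOW_ALTERNATE = HUWindow(-700.0, -400.0)


def threshold_segment(
    vol: CTVolume, window: HUWindow = WINDOW_REFERENCE, thorax_restrict: VOIMask | None = None
) -> VOIMask:
    """Segment aerated lung as voxels with ``low <= HU <= high``.

    After windowing (and optional restriction to a thoracic mask) the mask
    is cleaned of exterior air by removing connected components touching the
    volume border, and of noise specks below ``MIN_COMPONENT_VOXELS``.
    """
    if vol.units != "HU":
        raise ValueError("threshold segmentation requires an HU-calibrated volume")
    raw = (vol.data >= window.low) & (vol.data <= window.high)
    if thorax_restrict is not None:
        if not thorax_restrict.matches_grid(vol):
            raise ValueError("thorax restriction mask does not match the volume grid")
        raw &= thorax_restrict.data
    if not raw.any():
        raise ValueError("no voxels in window — check calibration")
    labels, n = ndimage.label(raw, structure=np.ones((3, 3, 3), dtype=bool))
    border = np.zeros_like(raw)
    border[0, :, :] = border[-1, :, :] = True
    border[:, 0, :] = border[:, -1, :] = True
    border[:, :, 0] = border[:, :, -1] = True
    touching = np.unique(labels[border & raw])
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    keep = counts >= MIN_COMPONENT_VOXELS
    keep[0] = False
    keep[touching] = False
    out = keep[labels]
    if not out.any():
        raise ValueError("no voxels in window — check calibration")
    return VOIMask(data=out, spacing=vol.spacing)


@dataclass
class SliceContourSet:
    """Closed polygons per annotated axial slice, in in-plane mm coordinates.

    ``contours`` maps axial slice index → list of polygons, each an
    ``(n, 2)`` array of ``(y, x)`` vertices in mm.  At least two slices must
    be annotated; the annotated extent bounds the delineation.
    """

    contours: dict[int, list[np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned: dict[int, list[np.ndarray]] = {}
        for idx in sorted(self.contours):
            polys = []
            for poly in self.contours[idx]:
                arr = np.asarray(poly, dtype=float)
                if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
                    raise ValueError("each polygon needs >= 3 (y, x) vertices")
                if not np.all(np.isfinite(arr)):
                    raise ValueError("polygon vertices must be finite")
                polys.append(arr)
            if polys:
                cleaned[int(idx)] = polys
        if len(cleaned) < 2:
            raise ValueError("need >= 2 annotated slices")
        self.contours = cleaned

    @property
    def extent(self) -> tuple[int, int]:
        keys = sorted(self.contours)
        return keys[0], keys[-1]

    def to_json(self, path: str) -> str:
        payload = {str(k): [p.tolist() for p in v] for k, v in self.contours.items()}
        with open(path, "w") as fh:
            json.dump(payload, fh)
        return path

    @classmethod
    def from_json(cls, path: str) -> "SliceContourSet":
        with open(path) as fh:
            payload = json.load(fh)
        return cls({int(k): [np.asarray(p, dtype=float) for p in v] for k, v in payload.items()})


def _rasterize_slice(polys: list[np.ndarray], shape: tuple[int, int], spacing: tuple[float, float]) -> np.ndarray:
    """Even-odd rasterization: polygons XOR together, so nested contours cut holes."""
    out = np.zeros(shape, dtype=bool)
    for poly in polys:
        idx_poly = poly / np.asarray(spacing)[None, :]
        out ^= draw.polygon2mask(shape, idx_poly)
    return out


def _signed_distance(mask2d: np.ndarray, sampling: tuple[float, float]) -> np.ndarray:
    """Negative inside the mask, positive outside, in mm."""
    if mask2d.all():
        return -ndimage.distance_transform_edt(mask2d, sampling=sampling)
    if not mask2d.any():
        return ndimage.distance_transform_edt(~mask2d, sampling=sampling)
    d_out = ndimage.distance_transform_edt(~mask2d, sampling=sampling)
    d_in = ndimage.distance_transform_edt(mask2d, sampling=sampling)
    return d_out - d_in


def delineate_from_contours(contours: SliceContourSet, grid: CTVolume) -> VOIMask:
    """Rasterize annotated slices and interpolate the gaps between them.

    Annotated slices are filled exactly (even-odd rule); an unannotated
    slice at fraction ``t`` between two annotated slices takes the region
    where the linear blend of their signed distance transforms is negative.
    The mask is empty outside the first/last annotated slice.
    """
    nz, ny, nx = grid.shape
    sy, sx = grid.spacing[1], grid.spacing[2]
    first, last = contours.extent
    if first < 0 or last >= nz:
        raise ValueError("annotated slices outside grid bounds")
    for idx, polys in contours.contours.items():
        for poly in polys:
            if (
                poly[:, 0].min() < -1e-9
                or poly[:, 1].min() < -1e-9
                or poly[:, 0].max() > (ny - 1) * sy + 1e-9
                or poly[:, 1].max() > (nx - 1) * sx + 1e-9
            ):
                raise ValueError(f"polygon out of bounds on slice {idx}")

    out = np.zeros(grid.shape, dtype=bool)
    keys = sorted(contours.contours)
    rasters = {k: _rasterize_slice(contours.contours[k], (ny, nx), (sy, sx)) for k in keys}
    for k in keys:
        out[k] = rasters[k]
    for a, b in zip(keys[:-1], keys[1:]):
        if b - a < 2:
            continue
        sdf_a = _signed_distance(rasters[a], (sy, sx))
        sdf_b = _signed_distance(rasters[b], (sy, sx))
        for k in range(a + 1, b):
            t = (k - a) / (b - a)
            out[k] = (1.0 - t) * sdf_a + t * sdf_b < 0.0
    return VOIMask(data=out, spacing=grid.spacing)


def mask_volume_mm3(mask: VOIMask) -> float:
    """Volume of a binary mask: 1-voxel count × voxel volume, in mm³."""
    return float(mask.data.sum()) * mask.voxel_volume_mm3


def contours_from_mask(mask: VOIMask, every: int = 2) -> SliceContourSet:
    """Extract slice contours from a mask, emulating an operator's drawing.

    Every ``every``-th slice carrying mask voxels is annotated (the first
    and last occupied slices always are) with sub-voxel iso-contours at
    level 0.5, converted to in-plane mm.  Feeding the result to
    :func:`delineate_from_contours` closes the manual-delineation loop in
    synthetic experiments.
    """
    if every < 1:
        raise ValueError("every must be >= 1")
    occupied = np.flatnonzero(mask.data.any(axis=(1, 2)))
    if occupied.size < 2:
        raise ValueError("mask spans fewer than 2 slices")
    chosen = sorted(set(occupied[::every].tolist()) | {int(occupied[0]), int(occupied[-1])})
    sy, sx = mask.spacing[1], mask.spacing[2]
    contours: dict[int, list[np.ndarray]] = {}
    for k in chosen:
        found = measure.find_contours(mask.data[k].astype(float), 0.5)
        polys = [c * np.array([sy, sx])[None, :] for c in found if c.shape[0] >= 3]
        if polys:
            contours[int(k)] = polys
    return SliceContourSet(contours)
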