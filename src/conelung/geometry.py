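"""Landmark-based thoracic measurements and the truncated-cone volume.

The thorax of a mouse is approximated by a conical frustum: the small base
sits at the carina (the division of the principal bronchi, measured in
coronal view from one external lung limit to the contralateral one), the
large base at the diaphragmatic cupola (measured in sagittal view from the
ventral aspect of the vertebrae to the abdominal wall) and the height spans
carina to diaphragm.  The frustum volume

    V = (π·h/3) · (R1² + R2² + R1·R2)

with R1, R2 the base radii then serves as the thoracic volume from which a
theoretical lung volume is predicted by linear regression
(:mod:`conelung.calibration_model`).

Landmark lines span the full thorax, so the measured distances are
diameters; radii are half the measured spans.  The halving convention is
exposed (``halve_diameters``) for sensitivity analysis — a constant factor
is absorbed by the downstream regression, but raw thoracic volumes depend
on it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ct_io import CTVolume

__all__ = [
    "ThoraxMeasure",
    "LandmarkSet",
    "measure_thorax",
    "truncated_cone_volume",
    "thoracic_volume_from_image",
    "voxelized_frustum_volume",
]


@dataclass(frozen=True)
class ThoraxMeasure:
    """The three landmark distances, in mm.

    ``d_small``: carina-level base span (coronal view),
    ``d_large``: diaphragm-level base span (sagittal view),
    ``height``: carina-to-diaphragm distance.
    """

    d_small: float
    d_large: float
    height: float

    def __post_init__(self) -> None:
        for name in ("d_small", "d_large", "height"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive distance in mm")


@dataclass(frozen=True)
class LandmarkSet:
    """Three point-pairs in physical (z, y, x) mm coordinates."""

    small_base: tuple[tuple[float, float, float], tuple[float, float, float]]
    large_base: tuple[tuple[float, float, float], tuple[float, float, float]]
    height: tuple[tuple[float, float, float], tuple[float, float, float]]

    def __post_init__(self) -> None:
        for name in ("small_base", "large_base", "height"):
            a, b = (np.asarray(p, dtype=float) for p in getattr(self, name))
            if a.shape != (3,) or b.shape != (3,):
                raise ValueError(f"{name} endpoints must be 3-D points")
            if np.allclose(a, b):
                raise ValueError(f"{name} endpoints coincide")

    def pairs(self):
        return {
            "small_base": self.small_base,
            "large_base": self.large_base,
            "height": self.height,
        }

    def all_points(self) -> np.ndarray:
        return np.array(
            [p for pair in (self.small_base, self.large_base, self.height) for p in pair],
            dtype=float,
        )

    def to_dict(self) -> dict:
        return {k: [list(map(float, p)) for p in v] for k, v in self.pairs().items()}

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkSet":
        return cls(
            small_base=tuple(tuple(p) for p in d["small_base"]),
            large_base=tuple(tuple(p) for p in d["large_base"]),
            height=tuple(tuple(p) for p in d["height"]),
        )


def _distance(pair) -> float:
    a, b = (np.asarray(p, dtype=float) for p in pair)
    return float(np.linalg.norm(a - b))


def measure_thorax(landmarks: LandmarkSet) -> ThoraxMeasure:
    """Euclidean distance of each landmark point-pair, in mm."""
    return ThoraxMeasure(
        d_small=_distance(landmarks.small_base),
        d_large=_distance(landmarks.large_base),
        height=_distance(landmarks.height),
    )


def truncated_cone_volume(m: ThoraxMeasure, halve_diameters: bool = True) -> float:
    """Conical-frustum volume (mm³) from the three thoracic measurements.

    ``V = (π·h/3)(R1² + R2² + R1·R2)`` with ``R1 = d_small/2`` and
    ``R2 = d_large/2`` under the default diameter-halving convention.
    The formula is symmetric in R1 ↔ R2 and strictly increasing in every
    measurement; ``d_small == d_large`` degenerates to a cylinder.
    """
    scale = 0.5 if halve_diameters else 1.0
    r1 = scale * m.d_small
    r2 = scale * m.d_large
    return float(np.pi * m.height / 3.0 * (r1 * r1 + r2 * r2 + r1 * r2))


def thoracic_volume_from_image(
    vol: CTVolume, landmarks: LandmarkSet, halve_diameters: bool = True
) -> tuple[ThoraxMeasure, float]:
    """Measure the landmarks placed on a (reoriented) volume and return the
    measurements together with the truncated-cone thoracic volume (mm³).

    Landmarks must lie inside the physical extent of the volume.
    """
    pts = landmarks.all_points()
    extent = np.asarray(vol.extent_mm)
    if np.any(pts < -1e-9) or np.any(pts > extent + 1e-9):
        raise ValueError("landmarks outside volume extent")
    m = measure_thorax(landmarks)
    return m, truncated_cone_volume(m, halve_diameters=halve_diameters)


def voxelized_frustum_volume(
    d_small: float, d_large: float, height: float, spacing: float = 0.05
) -> float:
    """Brute-force cross-check of the frustum volume by voxel counting.

    A circular frustum with linearly interpolated radius is rasterized on an
    isotropic grid of the given ``spacing`` (mm) and the in-solid voxel
    centers are counted.  Independent of :func:`truncated_cone_volume` —
    used to validate the analytic formula at mouse scale.
    """
    if min(d_small, d_large, height) <= 0 or spacing <= 0:
        raise ValueError("frustum dimensions and spacing must be positive")
    r1, r2 = d_small / 2.0, d_large / 2.0
    rmax = max(r1, r2)
    z = np.arange(spacing / 2.0, height, spacing)
    radii = r1 + (r2 - r1) * z / height
    half = int(np.ceil(rmax / spacing)) + 1
    coords = (np.arange(-half, half + 1) + 0.5) * spacing
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    rho2 = yy * yy + xx * xx
    counts = (rho2[None, :, :] <= (radii**2)[:, None, None]).sum(axis=(1, 2))
    return float(counts.sum()) * spacing**3
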