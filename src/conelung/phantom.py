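"""Synthetic mouse-thorax microCT phantoms with ground-truth manifests.

Every downstream stage of the protocol (HU calibration, threshold and
contour segmentation, landmark measurement, regression calibration,
agreement statistics) is testable without animal data through two
generators:

* :func:`generate_thorax_phantom` builds a mouse-like thorax: background
  air at −1000 HU, a soft-tissue body (≈40 HU) with vertebral column and
  rib shell (≥ +400 HU), a thoracic cavity shaped as a smooth
  truncated-cone-like solid of revolution with elliptical cross-section
  (so the landmark frustum model is a good but not perfect fit — the
  residual is left for the regression stage to absorb), lung parenchyma
  drawn from a truncated Gaussian with mode −500 HU supported on
  (−700, −300) HU, a tracheal air column, optional radiodense lesions
  (≈ +30 HU, nodular or consolidated), and additive Gaussian noise.
  The manifest volumes equal generator-mask voxel counts × voxel volume
  exactly.

* :func:`generate_calibration_phantom` emulates the air/water tube used
  for Hounsfield calibration: two disjoint cylindrical compartments with
  distinct raw grey means plus VOIs strictly inside each compartment.

:func:`generate_cohort` draws a population of thorax phantoms whose true
total lung volume follows ``lung = a·thoracic + b + ε`` (ε ~ Normal(0, sd²)),
realized by selecting the exact lung voxel count per phantom, so linear
structure between the truths holds to one-voxel rounding.

All randomness flows from a single integer seed; per-phantom sub-seeds are
derived deterministically, so identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage, stats

from .ct_io import CTVolume, VOIMask
from .geometry import LandmarkSet

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "ThoraxPhantom",
    "CohortPopulation",
    "generate_thorax_phantom",
    "generate_calibration_phantom",
    "generate_cohort",
]

# tissue intensities (HU)
HU_AIR = -1000.0
HU_BODY = 40.0
HU_MEDIASTINUM = 50.0
HU_VESSEL = 60.0
HU_LESION = 30.0
HU_BONE = 700.0
PARENCHYMA_MEAN = -500.0
PARENCHYMA_SD = 80.0
PARENCHYMA_LOW = -700.0
PARENCHYMA_HIGH = -300.0

_BODY_WALL_MM = 1.0
_CRANIAL_MARGIN_MM = 1.5
_CAUDAL_MARGIN_MM = 1.8


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic thorax.

    Geometry is given in mm: ``carina_width_mm`` is the cavity width at the
    carina level (small frustum base, left-right), ``diaphragm_depth_mm``
    the dorso-ventral cavity depth at the diaphragm (large base) and
    ``height_mm`` the carina-to-diaphragm distance.  ``dv_aspect`` is the
    dorso-ventral/left-right aspect ratio of the elliptical cross-section
    and ``bulge`` the fractional mid-thorax widening that keeps the cavity
    from being an exact frustum.  Fractions are of the enclosing mask:
    ``lung_fraction`` of the thoracic cavity, ``aeration_fraction`` and
    pathology ``burden_fraction`` of the lung.
    """

    shape: tuple[int, int, int] = (256, 256, 256)
    spacing: tuple[float, float, float] = (0.05, 0.05, 0.05)
    carina_width_mm: float = 6.0
    diaphragm_depth_mm: float = 7.6
    height_mm: float = 9.0
    lung_fraction: float = 0.62
    aeration_fraction: float = 0.88
    pathology: str = "none"
    burden_fraction: float = 0.0
    noise_sd_hu: float = 25.0
    seed: int = 0
    dv_aspect: float = 0.85
    bulge: float = 0.12
    target_lung_mm3: float | None = None  # overrides lung_fraction when set

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 8 for s in self.shape):
            raise ValueError("shape must be 3 axes of at least 8 voxels")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        for name in ("carina_width_mm", "diaphragm_depth_mm", "height_mm", "dv_aspect"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("lung_fraction", "aeration_fraction", "burden_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.burden_fraction > self.aeration_fraction:
            raise ValueError("pathology burden exceeds aeration headroom")
        if self.pathology not in ("none", "nodules", "consolidation"):
            raise ValueError(f"unknown pathology {self.pathology!r}")
        if self.pathology == "none" and self.burden_fraction > 0:
            raise ValueError("burden requires a pathology type")
        if self.noise_sd_hu < 0:
            raise ValueError("noise sd must be >= 0")


@dataclass(frozen=True)
class PhantomTruth:
    """Ground-truth manifest of one synthetic scan.

    Volumes are mm³ and equal the voxel count × voxel volume of the
    corresponding generator masks.  ``landmarks`` hold the frustum
    measurement lines in physical mm coordinates; ``rib_small_base`` is the
    rib-to-rib fallback span at carina level for scans where no lung is
    visible at that plane.
    """

    thoracic_volume_mm3: float
    lung_volume_mm3: float
    aerated_volume_mm3: float
    landmarks: LandmarkSet
    rib_small_base: tuple[tuple[float, float, float], tuple[float, float, float]]
    pathologic: bool

    def __post_init__(self) -> None:
        if not (
            self.aerated_volume_mm3 <= self.lung_volume_mm3 + 1e-9
            and self.lung_volume_mm3 <= self.thoracic_volume_mm3 + 1e-9
        ):
            raise ValueError("volume ordering aerated <= lung <= thoracic violated")

    def to_dict(self) -> dict:
        return {
            "thoracic_volume_mm3": self.thoracic_volume_mm3,
            "lung_volume_mm3": self.lung_volume_mm3,
            "aerated_volume_mm3": self.aerated_volume_mm3,
            "landmarks": self.landmarks.to_dict(),
            "rib_small_base": [list(p) for p in self.rib_small_base],
            "pathologic": self.pathologic,
        }


class ThoraxPhantom(NamedTuple):
    volume: CTVolume | None
    truth: PhantomTruth
    masks: dict[str, VOIMask]


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int, int]) -> np.ndarray:
    """Smooth Gaussian random field: coarse white noise, trilinearly upsampled."""
    coarse = tuple(max(2, s // 6) for s in shape)
    base = rng.standard_normal(coarse).astype(np.float32)
    factors = [s / c for s, c in zip(shape, coarse)]
    return ndimage.zoom(base, factors, order=1, mode="nearest", grid_mode=True)


def _take_top(values: np.ndarray, flat_index: np.ndarray, k: int) -> np.ndarray:
    """Flat indices of the ``k`` largest entries of ``values`` (exact count)."""
    if k <= 0:
        return flat_index[:0]
    if k >= values.size:
        return flat_index
    sel = np.argpartition(values, values.size - k)[values.size - k:]
    return flat_index[sel]


def generate_thorax_phantom(
    spec: PhantomSpec, render: bool = True, lung_target_fn=None
) -> ThoraxPhantom:
    """Render one synthetic thorax and its ground-truth manifest.

    Returns the HU volume, the manifest, and the internal generator masks
    (``body``, ``cavity``, ``lung``, ``aerated``, ``lesion``).  With
    ``render=False`` intensities are skipped (``volume`` is None) — the
    masks and manifest are identical either way.
    """
    nz, ny, nx = (int(s) for s in spec.shape)
    sz, sy, sx = spec.spacing
    ext_z, ext_y, ext_x = (nz - 1) * sz, (ny - 1) * sy, (nx - 1) * sx
    h = spec.height_mm
    z0 = (ext_z - h) / 2.0
    z1 = z0 + h
    if z0 - _CRANIAL_MARGIN_MM < sz or z1 + _CAUDAL_MARGIN_MM > ext_z - sz:
        raise ValueError("thorax height does not fit the grid")
    yc, xc = ext_y / 2.0, ext_x / 2.0
    a0 = spec.carina_width_mm / 2.0
    b1 = spec.diaphragm_depth_mm / 2.0
    a1 = b1 / spec.dv_aspect

    z = np.arange(nz, dtype=np.float32) * sz
    y = np.arange(ny, dtype=np.float32) * sy
    x = np.arange(nx, dtype=np.float32) * sx
    t = np.clip((z - z0) / h, 0.0, 1.0)
    profile = (a0 + (a1 - a0) * t) * (1.0 + spec.bulge * np.sin(np.pi * t))
    a_z = profile.astype(np.float32)
    b_z = (spec.dv_aspect * profile).astype(np.float32)

    semi_x = float(profile.max()) + _BODY_WALL_MM
    semi_y = float(spec.dv_aspect * profile.max()) + _BODY_WALL_MM
    if xc - semi_x < sx or xc + semi_x > ext_x - sx or yc - semi_y < sy or yc + semi_y > ext_y - sy:
        raise ValueError("thorax geometry does not fit the grid")

    X2 = ((x - xc) ** 2).astype(np.float32)
    Y2 = ((y - yc) ** 2).astype(np.float32)
    in_z = (z >= z0 - 1e-9) & (z <= z1 + 1e-9)
    rho2 = (
        Y2[None, :, None] / (b_z**2)[:, None, None]
        + X2[None, None, :] / (a_z**2)[:, None, None]
    )
    cavity = (rho2 <= 1.0) & in_z[:, None, None]
    n_cav = int(cavity.sum())
    if n_cav == 0:
        raise ValueError("thoracic cavity is empty on this grid")
    voxvol = float(sz * sy * sx)

    body2d = (Y2[:, None] / semi_y**2 + X2[None, :] / semi_x**2) <= 1.0
    body_z = (z >= z0 - _CRANIAL_MARGIN_MM) & (z <= z1 + _CAUDAL_MARGIN_MM)
    body = body2d[None, :, :] & body_z[:, None, None]
    body |= cavity

    # lung = outermost fraction of the cavity; the spared central core plays
    # the mediastinum/heart.  Selection by normalized elliptical radius gives
    # the exact requested voxel count.
    cav_idx = np.flatnonzero(cavity.ravel())
    cav_rho = rho2.ravel()[cav_idx]
    if lung_target_fn is not None:
        # target evaluated on the voxelized thoracic volume, so linear
        # cohort structure holds exactly on the manifest truths
        n_lung = int(round(float(lung_target_fn(n_cav * voxvol)) / voxvol))
    elif spec.target_lung_mm3 is not None:
        n_lung = int(round(spec.target_lung_mm3 / voxvol))
    else:
        n_lung = int(round(spec.lung_fraction * n_cav))
    if not (0.02 * n_cav <= n_lung <= 0.95 * n_cav):
        raise ValueError(
            "requested lung volume infeasible for this thorax "
            f"(wants {n_lung} of {n_cav} cavity voxels)"
        )
    lung_idx = _take_top(cav_rho, cav_idx, n_lung)
    lung = np.zeros(cavity.shape, dtype=bool)
    lung.ravel()[lung_idx] = True

    rng = np.random.default_rng(spec.seed)
    n_lesion = int(round(spec.burden_fraction * n_lung))
    n_vessel = int(round((1.0 - spec.aeration_fraction) * n_lung))
    lesion = np.zeros(cavity.shape, dtype=bool)
    vessel = np.zeros(cavity.shape, dtype=bool)
    if n_lesion > 0:
        f = _smooth_field(rng, (nz, ny, nx))
        if spec.pathology == "consolidation":
            # bias toward the dorso-caudal lung so the burden is contiguous
            f = f * 0.3 + (
                (z[:, None, None] - z0) / h + (y[None, :, None] - yc) / max(semi_y, 1e-6)
            ).astype(np.float32)
        les_idx = _take_top(f.ravel()[lung_idx], lung_idx, n_lesion)
        lesion.ravel()[les_idx] = True
    if n_vessel > 0:
        fv = _smooth_field(rng, (nz, ny, nx))
        free_idx = lung_idx[~lesion.ravel()[lung_idx]]
        ves_idx = _take_top(fv.ravel()[free_idx], free_idx, n_vessel)
        vessel.ravel()[ves_idx] = True
    aerated = lung & ~lesion & ~vessel

    landmarks = LandmarkSet(
        small_base=((z0, yc, xc - a0), (z0, yc, xc + a0)),
        large_base=((z1, yc - b1, xc), (z1, yc + b1, xc)),
        height=((z0, yc, xc), (z1, yc, xc)),
    )
    rib_half = 0.92 * semi_x
    truth = PhantomTruth(
        thoracic_volume_mm3=n_cav * voxvol,
        lung_volume_mm3=n_lung * voxvol,
        aerated_volume_mm3=int(aerated.sum()) * voxvol,
        landmarks=landmarks,
        rib_small_base=((z0, yc, xc - rib_half), (z0, yc, xc + rib_half)),
        pathologic=spec.pathology != "none",
    )
    masks = {
        "body": VOIMask(body, spec.spacing),
        "cavity": VOIMask(cavity, spec.spacing),
        "lung": VOIMask(lung, spec.spacing),
        "aerated": VOIMask(aerated, spec.spacing),
        "lesion": VOIMask(lesion, spec.spacing),
    }
    if not render:
        return ThoraxPhantom(volume=None, truth=truth, masks=masks)

    vol = np.full((nz, ny, nx), HU_AIR, dtype=np.float32)
    vol[body] = HU_BODY
    vol[cavity & ~lung] = HU_MEDIASTINUM
    vol[vessel] = HU_VESSEL
    vol[lesion] = HU_LESION
    n_aer = int(aerated.sum())
    if n_aer:
        lo = (PARENCHYMA_LOW - PARENCHYMA_MEAN) / PARENCHYMA_SD
        hi = (PARENCHYMA_HIGH - PARENCHYMA_MEAN) / PARENCHYMA_SD
        vol[aerated] = stats.truncnorm.rvs(
            lo, hi, loc=PARENCHYMA_MEAN, scale=PARENCHYMA_SD, size=n_aer, random_state=rng
        ).astype(np.float32)

    # trachea: air column from the cranial body margin down to the carina
    trachea_r = 0.4
    trachea2d = (Y2[:, None] + X2[None, :]) <= trachea_r**2
    trachea_z = (z >= z0 - _CRANIAL_MARGIN_MM) & (z < z0)
    vol[trachea2d[None, :, :] & trachea_z[:, None, None]] = HU_AIR

    # bone: dorsal vertebral column plus periodic rib shell in the body wall
    vert_r = 0.4
    vert2d = ((y - (yc + semi_y - 0.5)) ** 2)[:, None] + X2[None, :] <= vert_r**2
    vol[vert2d[None, :, :] & body_z[:, None, None] & body] = HU_BONE
    brho2 = Y2[:, None] / semi_y**2 + X2[None, :] / semi_x**2
    rib2d = (brho2 > 0.92**2) & (brho2 <= 1.0)
    rib_z = in_z & (np.sin(2.0 * np.pi * z / 1.2) > 0.45)
    vol[rib2d[None, :, :] & rib_z[:, None, None] & ~cavity] = HU_BONE

    if spec.noise_sd_hu > 0:
        vol += rng.normal(0.0, spec.noise_sd_hu, size=vol.shape).astype(np.float32)

    ct = CTVolume(data=vol, spacing=spec.spacing, units="HU")
    return ThoraxPhantom(volume=ct, truth=truth, masks=masks)


# ---------------------------------------------------------------------------
# air/water calibration tube


def generate_calibration_phantom(
    shape: tuple[int, int, int] = (96, 72, 72),
    spacing: tuple[float, float, float] = (0.05, 0.05, 0.05),
    air_grey: int = 10000,
    water_grey: int = 30000,
    background_grey: int = 5000,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[CTVolume, VOIMask, VOIMask]:
    """Synthetic calibration tube: stacked air and water compartments.

    Two non-overlapping cylinders with the designed raw grey means are
    rendered with optional Gaussian noise (rounded back to non-negative
    integers); the returned VOIs lie strictly inside each compartment.
    """
    nz, ny, nx = (int(s) for s in shape)
    if nz < 24 or ny < 16 or nx < 16:
        raise ValueError("grid too small for two compartments")
    if water_grey <= air_grey:
        raise ValueError("water grey must exceed air grey")
    tube_r = min(ny, nx) // 2 - 2
    half = nz // 2
    air_lo, air_hi = 2, half - 2
    wat_lo, wat_hi = half + 2, nz - 2
    if air_hi <= air_lo or wat_hi <= wat_lo or air_hi >= wat_lo:
        raise ValueError("compartments would overlap")

    yy, xx = np.meshgrid(np.arange(ny) - (ny - 1) / 2, np.arange(nx) - (nx - 1) / 2, indexing="ij")
    in_tube = yy**2 + xx**2 <= tube_r**2
    data = np.full((nz, ny, nx), float(background_grey), dtype=np.float64)
    data[air_lo:air_hi, in_tube] = air_grey
    data[wat_lo:wat_hi, in_tube] = water_grey

    voi_r = max(2, tube_r - 4)
    in_voi = yy**2 + xx**2 <= voi_r**2
    air_mask = np.zeros((nz, ny, nx), dtype=bool)
    water_mask = np.zeros((nz, ny, nx), dtype=bool)
    air_mask[air_lo + 2 : air_hi - 2, in_voi] = True
    water_mask[wat_lo + 2 : wat_hi - 2, in_voi] = True

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data += rng.normal(0.0, noise_sd, size=data.shape)
    grey = np.rint(data).clip(min=0).astype(np.int32)
    vol = CTVolume(data=grey, spacing=spacing, units="raw_grey")
    return vol, VOIMask(air_mask, spacing), VOIMask(water_mask, spacing)


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CohortPopulation:
    """Population distributions for cohort phantoms.

    Thoracic cavity volumes are drawn from a truncated Normal (mm³) chosen
    to mirror the spread of healthy adult mice (mean ≈ 900 mm³, CV ≈ 21%,
    truncated below so the regression target stays feasible); shape ratios
    and heights vary uniformly.  The cavity width solving for the drawn
    volume is found from the analytic solid-of-revolution volume.
    """

    shape: tuple[int, int, int] = (160, 192, 224)
    spacing: tuple[float, float, float] = (0.1, 0.1, 0.1)
    thoracic_mean_mm3: float = 900.0
    thoracic_sd_mm3: float = 190.0
    thoracic_bounds_mm3: tuple[float, float] = (520.0, 1450.0)
    height_range_mm: tuple[float, float] = (9.0, 12.0)
    taper_range: tuple[float, float] = (1.35, 1.6)  # a1/a0 ratio
    dv_aspect: float = 0.85
    bulge: float = 0.12
    aeration_fraction: float = 0.88
    noise_sd_hu: float = 25.0

    def draw_geometry(self, rng: np.random.Generator):
        lo, hi = self.thoracic_bounds_mm3
        a = (lo - self.thoracic_mean_mm3) / self.thoracic_sd_mm3
        b = (hi - self.thoracic_mean_mm3) / self.thoracic_sd_mm3
        v = float(
            stats.truncnorm.rvs(
                a, b, loc=self.thoracic_mean_mm3, scale=self.thoracic_sd_mm3, random_state=rng
            )
        )
        h = float(rng.uniform(*self.height_range_mm))
        k = float(rng.uniform(*self.taper_range))
        # analytic cavity volume: V = pi * dv * h * a0^2 * I(k, bulge)
        tt = np.linspace(0.0, 1.0, 513)
        integrand = ((1.0 + (k - 1.0) * tt) * (1.0 + self.bulge * np.sin(np.pi * tt))) ** 2
        integral = float(np.trapezoid(integrand, tt))
        a0 = np.sqrt(v / (np.pi * self.dv_aspect * h * integral))
        return v, 2.0 * a0, 2.0 * self.dv_aspect * (k * a0), h


def generate_cohort(
    n: int,
    population: CohortPopulation | None = None,
    slope: float = 0.20,
    intercept: float = 300.0,
    noise_sd: float = 20.0,
    seed: int = 0,
    render_volumes: bool = True,
    pathology: str = "none",
    burden_fraction: float = 0.0,
) -> list[ThoraxPhantom]:
    """Draw ``n`` phantoms whose lung/thoracic truths follow a known line.

    Per phantom, the true total lung volume target is
    ``slope · thoracic + intercept + ε`` with ε ~ Normal(0, ``noise_sd``²);
    the generator realizes it by selecting the exact corresponding voxel
    count, so at ``noise_sd = 0`` an OLS fit of the truths recovers
    (slope, intercept) to one-voxel rounding.  With ``render_volumes=False``
    only masks and manifests are produced (fast path for statistical
    experiments that never touch intensities).
    """
    if n < 3:
        raise ValueError("need >= 3 phantoms for a cohort")
    if not 0.0 < slope <= 1.0:
        raise ValueError("slope must be in (0, 1]")
    if intercept < 0:
        raise ValueError("intercept must be >= 0")
    pop = population or CohortPopulation()
    rng = np.random.default_rng(seed)
    out: list[ThoraxPhantom] = []
    for _ in range(n):
        v_analytic, carina_w, diaphragm_d, h = pop.draw_geometry(rng)
        eps = float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0
        sub_seed = int(rng.integers(0, 2**31 - 1))
        if not 0.05 * v_analytic < slope * v_analytic + intercept + eps < 0.95 * v_analytic:
            raise ValueError(
                f"requested (a={slope}, b={intercept}) infeasible for the "
                f"thorax size distribution (thoracic {v_analytic:.0f} mm3)"
            )
        spec = PhantomSpec(
            shape=pop.shape,
            spacing=pop.spacing,
            carina_width_mm=carina_w,
            diaphragm_depth_mm=diaphragm_d,
            height_mm=h,
            aeration_fraction=pop.aeration_fraction,
            pathology=pathology,
            burden_fraction=burden_fraction,
            noise_sd_hu=pop.noise_sd_hu if render_volumes else 0.0,
            seed=sub_seed,
            dv_aspect=pop.dv_aspect,
            bulge=pop.bulge,
        )
        out.append(
            generate_thorax_phantom(
                spec,
                render=render_volumes,
                lung_target_fn=lambda v, e=eps: slope * v + intercept + e,
            )
        )
    return out
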