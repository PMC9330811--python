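"""Hounsfield-unit calibration from air and water VOI means.

A two-point linear map anchors the arithmetic mean grey value of an air VOI
to −1000 HU and of a water VOI to 0 HU, per the standard tube-phantom
protocol.  Means are plain arithmetic means over all mask voxels — no
trimming or robustification.  Calibrations are per scan session and can be
persisted as JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .ct_io import CTVolume, VOIMask

__all__ = ["HUCalibration", "fit_hu_calibration", "apply_hu_calibration"]

AIR_HU = -1000.0
WATER_HU = 0.0


@dataclass(frozen=True)
class HUCalibration:
    """Linear grey→HU map: ``HU = slope * grey + intercept``."""

    slope: float
    intercept: float
    air_mean: float
    water_mean: float

    def __post_init__(self) -> None:
        if self.water_mean == self.air_mean:
            raise ValueError("water and air means must differ")
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        # anchor invariants, to floating tolerance
        if abs(self.slope * self.air_mean + self.intercept - AIR_HU) > 1e-6:
            raise ValueError("calibration does not map air mean to -1000 HU")
        if abs(self.slope * self.water_mean + self.intercept - WATER_HU) > 1e-6:
            raise ValueError("calibration does not map water mean to 0 HU")

    def __call__(self, grey):
        return self.slope * np.asarray(grey, dtype=np.float64) + self.intercept

    def to_json(self, path: str) -> str:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
        return path

    @classmethod
    def from_json(cls, path: str) -> "HUCalibration":
        with open(path) as fh:
            return cls(**json.load(fh))


def fit_hu_calibration(vol: CTVolume, air: VOIMask, water: VOIMask) -> HUCalibration:
    """Fit the two-point grey→HU map from air and water VOIs on a raw scan.

    ``slope = 1000 / (mean_water − mean_air)`` and the intercept places the
    water mean at exactly 0 HU.
    """
    if vol.units != "raw_grey":
        raise ValueError("calibration is fitted on raw grey volumes")
    for name, voi in (("air", air), ("water", water)):
        if not voi.matches_grid(vol):
            raise ValueError(f"{name} VOI grid does not match the volume")
        if not voi.data.any():
            raise ValueError(f"{name} VOI is empty")
    air_mean = float(vol.data[air.data].mean())
    water_mean = float(vol.data[water.data].mean())
    if water_mean <= air_mean:
        raise ValueError("VOIs inverted or degenerate: mean(water) <= mean(air)")
    slope = (WATER_HU - AIR_HU) / (water_mean - air_mean)
    intercept = WATER_HU - slope * water_mean
    return HUCalibration(slope=slope, intercept=intercept, air_mean=air_mean, water_mean=water_mean)


def apply_hu_calibration(vol: CTVolume, cal: HUCalibration) -> CTVolume:
    """Apply a fitted calibration voxel-wise; spacing and shape unchanged."""
    if vol.units == "HU":
        raise ValueError("double calibration: volume is already in HU")
    hu = (cal.slope * vol.data.astype(np.float64) + cal.intercept).astype(np.float32)
    return CTVolume(data=hu, spacing=vol.spacing, units="HU", orientation=vol.orientation)
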