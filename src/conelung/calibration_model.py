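"""Linear calibration from thoracic (frustum) volume to lung volume.

The protocol's endpoint: an ordinary least-squares line fitted between the
truncated-cone thoracic volume and the manually delineated total lung
volume of a calibration cohort.  Applying the line to a new thoracic volume
yields the *theoretical lung volume*.  Calibration is intended per animal
model; predicting outside the training volume range warns (pathologic
thoraces routinely exceed the healthy range) rather than failing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

__all__ = [
    "RegressionModel",
    "ExtrapolationWarning",
    "fit_lung_regression",
    "predict_theoretical_lung",
    "percent_deviation",
]


class ExtrapolationWarning(UserWarning):
    """Prediction requested outside the training thoracic-volume range."""


@dataclass(frozen=True)
class RegressionModel:
    """OLS line ``lung = slope * thoracic + intercept`` with diagnostics.

    ``slope`` is dimensionless, ``intercept`` in mm³; ``r_squared`` equals
    the squared Pearson correlation of the training pairs.
    """

    slope: float
    intercept: float
    r_squared: float
    pearson_r: float
    p_value: float
    n: int
    training_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("model requires n >= 3 training pairs")
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise ValueError("r_squared must lie in [0, 1]")
        if abs(self.r_squared - self.pearson_r**2) > 1e-9:
            raise ValueError("r_squared inconsistent with pearson_r")

    def to_json(self, path: str) -> str:
        payload = asdict(self)
        payload["training_range"] = list(self.training_range)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        return path

    @classmethod
    def from_json(cls, path: str) -> "RegressionModel":
        with open(path) as fh:
            payload = json.load(fh)
        payload["training_range"] = tuple(payload["training_range"])
        return cls(**payload)


def fit_lung_regression(pairs) -> RegressionModel:
    """Fit lung volume on thoracic volume by ordinary least squares.

    ``pairs`` is a sequence of ``(thoracic_mm3, lung_mm3)`` tuples (or an
    ``(n, 2)`` array).  Pearson correlation supplies r and the p-value of
    the association; the fit is order-invariant.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (thoracic, lung) tuples")
    if arr.shape[0] < 3:
        raise ValueError("need >= 3 pairs to fit the calibration line")
    thoracic, lung = arr[:, 0], arr[:, 1]
    if np.ptp(thoracic) == 0:
        raise ValueError("zero variance in thoracic volumes")
    res = stats.linregress(thoracic, lung)
    return RegressionModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
        n=int(arr.shape[0]),
        training_range=(float(thoracic.min()), float(thoracic.max())),
    )


def predict_theoretical_lung(model: RegressionModel, thoracic: float) -> float:
    """Theoretical lung volume (mm³) for a thoracic volume (mm³).

    Warns with :class:`ExtrapolationWarning` when ``thoracic`` lies outside
    the training range.
    """
    if not np.isfinite(thoracic) or thoracic <= 0:
        raise ValueError("thoracic volume must be positive")
    lo, hi = model.training_range
    if thoracic < lo or thoracic > hi:
        warnings.warn(
            f"thoracic volume {thoracic:.1f} mm3 outside training range "
            f"[{lo:.1f}, {hi:.1f}] mm3",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return float(model.slope * thoracic + model.intercept)


def percent_deviation(theoretical: float, gold: float) -> float:
    """Absolute percent deviation of a prediction from the gold standard:
    ``100 * |theoretical - gold| / gold`` (magnitudes only, direction-free)."""
    if not np.isfinite(gold) or gold <= 0:
        raise ValueError("gold-standard volume must be positive")
    return float(100.0 * abs(theoretical - gold) / gold)
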