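"""Validation battery: volume ratios, Bland-Altman agreement, Gage R&R
variance components and the 5%-deviation sensitivity/specificity rule.

These are the statistics used to decide whether the theoretical lung
volume can replace manual delineation:

* per-scan volume ratios normalize out animal size,
* Bland-Altman quantifies bias and 95% limits of agreement between the
  theoretical and gold-standard volumes,
* a crossed two-way Gage R&R ANOVA decomposes measurement variance into
  part, operator, operator×part interaction and repeatability,
* each scan's deviation from the control-population mean lung volume,
  thresholded strictly at 5%, classifies it TP/FN/FP/TN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration_model import percent_deviation

__all__ = [
    "VolumeRecord",
    "VolumeRatios",
    "volume_ratios",
    "BlandAltmanResult",
    "bland_altman",
    "bland_altman_plot",
    "GageRRResult",
    "gage_rr",
    "ClassificationResult",
    "classify_cohort",
]


@dataclass
class VolumeRecord:
    """Per-scan volumes (mm³) with group label.

    ``group`` is one of ``pathologic``, ``negative-control`` or
    ``healthy``; ``theoretical_mm3`` stays None until predicted.
    """

    scan_id: str
    group: str
    thoracic_mm3: float
    manual_mm3: float
    threshold_mm3: float
    theoretical_mm3: float | None = None

    def __post_init__(self) -> None:
        if self.group not in ("pathologic", "negative-control", "healthy"):
            raise ValueError(f"unknown group {self.group!r}")
        for name in ("thoracic_mm3", "manual_mm3", "threshold_mm3", "theoretical_mm3"):
            v = getattr(self, name)
            if v is not None and (not np.isfinite(v) or v <= 0):
                raise ValueError(f"{name} must be positive when present")


@dataclass(frozen=True)
class VolumeRatios:
    """The three size-normalizing ratios, in percent.

    ``anomalous`` flags a thresholded (aerated) volume exceeding the manual
    total lung volume — physically impossible, so worth surfacing.
    """

    manual_over_thoracic_pct: float
    threshold_over_manual_pct: float
    threshold_over_thoracic_pct: float
    anomalous: bool


def volume_ratios(rec: VolumeRecord) -> VolumeRatios:
    """Percent ratios manual/thoracic, threshold/manual, threshold/thoracic."""
    for name in ("thoracic_mm3", "manual_mm3", "threshold_mm3"):
        if getattr(rec, name) is None:
            raise ValueError(f"missing volume {name}")
    return VolumeRatios(
        manual_over_thoracic_pct=100.0 * rec.manual_mm3 / rec.thoracic_mm3,
        threshold_over_manual_pct=100.0 * rec.threshold_mm3 / rec.manual_mm3,
        threshold_over_thoracic_pct=100.0 * rec.threshold_mm3 / rec.thoracic_mm3,
        anomalous=rec.threshold_mm3 > rec.manual_mm3,
    )


# ---------------------------------------------------------------------------
# Bland-Altman


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias and 95% limits of agreement between two paired series (mm³).

    Limits are ``bias ± 1.96 · sd`` with the sample standard deviation
    (n−1); ``points`` holds the per-pair (mean, difference) coordinates of
    the agreement plot.
    """

    bias: float
    sd: float
    lower_limit: float
    upper_limit: float
    n: int
    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.lower_limit - 1e-9 <= self.bias <= self.upper_limit + 1e-9:
            raise ValueError("bias outside limits of agreement")
        half = 1.96 * self.sd
        if abs(self.upper_limit - self.bias - half) > 1e-9 or abs(
            self.bias - self.lower_limit - half
        ) > 1e-9:
            raise ValueError("limits are not bias ± 1.96·sd")


def bland_altman(a, b) -> BlandAltmanResult:
    """Agreement of paired series ``a`` and ``b``: differences ``a − b``
    against pair means, with bias and normal-theory 95% limits."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and the same length")
    if a.size < 2:
        raise ValueError("need n >= 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        sd=sd,
        lower_limit=bias - 1.96 * sd,
        upper_limit=bias + 1.96 * sd,
        n=int(a.size),
        points=tuple(((ai + bi) / 2.0, di) for ai, bi, di in zip(a, b, d)),
    )


def bland_altman_plot(result: BlandAltmanResult, path: str, title: str = "Bland-Altman") -> str:
    """Write the agreement plot (mean vs difference with bias and limits)."""
    import matplotlib

    matplotlib.use("Agg")
    matplotlib.rcParams["svg.hashsalt"] = "conelung"  # reproducible SVG ids
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    pts = np.array(result.points)
    ax.scatter(pts[:, 0], pts[:, 1], s=18, color="#29516d")
    ax.axhline(result.bias, color="red", lw=1.2, label=f"bias {result.bias:.2f}")
    for lim in (result.lower_limit, result.upper_limit):
        ax.axhline(lim, color="grey", lw=1.0, ls="--")
    ax.set_xlabel("mean of methods (mm$^3$)")
    ax.set_ylabel("difference (mm$^3$)")
    ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)
    return path


# ---------------------------------------------------------------------------
# Gage R&R


@dataclass(frozen=True)
class GageRRResult:
    """ANOVA-method Gage R&R variance components.

    Variance components (measurement units squared) for part, operator,
    operator×part interaction and repeatability, with percent contribution
    of each to total variation.  ``operator_contribution_pct`` is the
    headline reproducibility figure: operator plus interaction shares.
    """

    var_part: float
    var_operator: float
    var_interaction: float
    var_repeatability: float
    pct_part: float
    pct_operator: float
    pct_interaction: float
    pct_repeatability: float
    n_parts: int
    n_operators: int
    n_replicates: int

    def __post_init__(self) -> None:
        for name in ("var_part", "var_operator", "var_interaction", "var_repeatability"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        total = self.pct_part + self.pct_operator + self.pct_interaction + self.pct_repeatability
        if abs(total - 100.0) > 1e-6:
            raise ValueError("percent contributions must sum to 100")

    @property
    def operator_contribution_pct(self) -> float:
        return self.pct_operator + self.pct_interaction


def gage_rr(data: pd.DataFrame) -> GageRRResult:
    """Two-way crossed Gage R&R ANOVA with interaction.

    ``data`` needs columns ``part``, ``operator``, ``replicate`` and
    ``measurement`` forming a balanced crossed design (every operator
    measures every part the same number of times; ≥2 parts, ≥2 operators,
    ≥2 replicates).  Variance components come from the standard
    expected-mean-squares equations; negative estimates are truncated to
    zero, and when the interaction mean square falls below the error mean
    square the interaction is pooled into repeatability before the
    remaining components are solved.
    """
    df = pd.DataFrame(data)
    required = {"part", "operator", "replicate", "measurement"}
    if not required.issubset(df.columns):
        raise ValueError(f"data must have columns {sorted(required)}")
    parts = df["part"].unique()
    ops = df["operator"].unique()
    p, o = len(parts), len(ops)
    if p < 2:
        raise ValueError("need >= 2 parts")
    if o < 2:
        raise ValueError("need >= 2 operators")
    counts = df.groupby(["part", "operator"], sort=False)["measurement"].count()
    r = int(counts.iloc[0])
    if r < 2:
        raise ValueError("need >= 2 replicates")
    if counts.nunique() != 1 or len(counts) != p * o:
        raise ValueError("unbalanced design: every operator must measure every part equally often")

    y = df["measurement"].to_numpy(dtype=float)
    grand = y.mean()
    part_means = df.groupby("part", sort=False)["measurement"].mean()
    op_means = df.groupby("operator", sort=False)["measurement"].mean()
    cell_means = df.groupby(["part", "operator"], sort=False)["measurement"].mean()

    ss_part = o * r * float(((part_means - grand) ** 2).sum())
    ss_op = p * r * float(((op_means - grand) ** 2).sum())
    ss_cell = r * float(((cell_means - grand) ** 2).sum())
    ss_int = ss_cell - ss_part - ss_op
    ss_tot = float(((y - grand) ** 2).sum())
    ss_err = ss_tot - ss_cell

    df_part, df_op = p - 1, o - 1
    df_int = (p - 1) * (o - 1)
    df_err = p * o * (r - 1)
    ms_part = ss_part / df_part
    ms_op = ss_op / df_op
    ms_int = ss_int / df_int
    ms_err = ss_err / df_err

    if ms_int < ms_err:
        # interaction indistinguishable from noise: pool into repeatability
        ms_pooled = (ss_int + ss_err) / (df_int + df_err)
        var_rep = ms_pooled
        var_int = 0.0
        var_op = max((ms_op - ms_pooled) / (p * r), 0.0)
        var_part = max((ms_part - ms_pooled) / (o * r), 0.0)
    else:
        var_rep = ms_err
        var_int = max((ms_int - ms_err) / r, 0.0)
        var_op = max((ms_op - ms_int) / (p * r), 0.0)
        var_part = max((ms_part - ms_int) / (o * r), 0.0)

    total = var_part + var_op + var_int + var_rep
    if total <= 0:
        # perfectly constant data: attribute everything to repeatability
        pct = (0.0, 0.0, 0.0, 100.0)
    else:
        pct = tuple(100.0 * v / total for v in (var_part, var_op, var_int, var_rep))
    return GageRRResult(
        var_part=var_part,
        var_operator=var_op,
        var_interaction=var_int,
        var_repeatability=var_rep,
        pct_part=pct[0],
        pct_operator=pct[1],
        pct_interaction=pct[2],
        pct_repeatability=pct[3],
        n_parts=p,
        n_operators=o,
        n_replicates=r,
    )


# ---------------------------------------------------------------------------
# sensitivity / specificity


@dataclass(frozen=True)
class ClassificationResult:
    """Outcome of the 5%-deviation screening rule.

    ``classes`` maps scan id → TP/FN/FP/TN; pathologic scans deviating
    more than ``threshold_pct`` from the control-population reference are
    true positives, controls staying within it are true negatives.  The
    boundary is strict: a deviation of exactly the threshold is negative.
    """

    classes: dict[str, str]
    sensitivity_pct: float
    specificity_pct: float
    reference_mm3: float
    threshold_pct: float
    counts: dict[str, int] = field(default_factory=dict)


def classify_cohort(records, reference="auto", threshold_pct: float = 5.0) -> ClassificationResult:
    """Classify scans by percent deviation of lung volume from a reference.

    ``records`` is a sequence of ``(scan_id, pathologic, lung_volume_mm3)``
    tuples.  ``reference`` is a population lung volume in mm³ or ``"auto"``
    to use the mean of the non-pathologic records.  Deviations strictly
    over ``threshold_pct`` are called positive.
    """
    if threshold_pct < 0:
        raise ValueError("threshold must be >= 0")
    recs = [(str(s), bool(p), float(v)) for s, p, v in records]
    if not recs:
        raise ValueError("no records")
    if reference == "auto":
        ctrl = [v for _, p, v in recs if not p]
        if not ctrl:
            raise ValueError("reference='auto' needs at least one non-pathologic record")
        ref = float(np.mean(ctrl))
    else:
        ref = float(reference)
        if ref <= 0:
            raise ValueError("reference volume must be positive")
    classes: dict[str, str] = {}
    counts = {"TP": 0, "FN": 0, "FP": 0, "TN": 0}
    for scan_id, pathologic, vol in recs:
        dev = percent_deviation(vol, ref)
        positive = dev > threshold_pct
        if pathologic:
            cls = "TP" if positive else "FN"
        else:
            cls = "FP" if positive else "TN"
        classes[scan_id] = cls
        counts[cls] += 1
    tp, fn, fp, tn = counts["TP"], counts["FN"], counts["FP"], counts["TN"]
    sensitivity = 100.0 * tp / (tp + fn) if (tp + fn) else float("nan")
    specificity = 100.0 * tn / (tn + fp) if (tn + fp) else float("nan")
    return ClassificationResult(
        classes=classes,
        sensitivity_pct=sensitivity,
        specificity_pct=specificity,
        reference_mm3=ref,
        threshold_pct=float(threshold_pct),
        counts=counts,
    )
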