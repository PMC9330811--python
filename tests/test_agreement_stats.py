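"""Volume ratios, Bland-Altman, Gage R&R and the 5%-deviation rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from conelung import (
    VolumeRecord,
    bland_altman,
    classify_cohort,
    gage_rr,
    volume_ratios,
)


def _record(thoracic=800.0, manual=520.0, threshold=450.0):
    return VolumeRecord(
        scan_id="s1", group="healthy",
        thoracic_mm3=thoracic, manual_mm3=manual, threshold_mm3=threshold,
    )


def test_volume_ratios_arithmetic():
    r = volume_ratios(_record())
    assert r.manual_over_thoracic_pct == pytest.approx(65.0)
    assert r.threshold_over_manual_pct == pytest.approx(86.54, abs=0.01)
    assert r.threshold_over_thoracic_pct == pytest.approx(56.25)
    assert not r.anomalous


def test_volume_ratios_flags_aerated_above_manual():
    r = volume_ratios(_record(manual=400.0, threshold=450.0))
    assert r.threshold_over_manual_pct > 100.0
    assert r.anomalous


def test_equal_manual_and_thoracic_gives_100():
    r = volume_ratios(_record(thoracic=520.0, manual=520.0))
    assert r.manual_over_thoracic_pct == pytest.approx(100.0)


# -- Bland-Altman -----------------------------------------------------------


def test_bland_altman_identical_series_is_zero():
    a = np.array([3.0, 5.0, 9.0, 11.0])
    res = bland_altman(a, a)
    assert res.bias == 0.0 and res.sd == 0.0
    assert res.lower_limit == 0.0 and res.upper_limit == 0.0


def test_bland_altman_closed_form():
    res = bland_altman(np.array([2.0, 4.0, 6.0]), np.array([1.0, 2.0, 3.0]))  # d = 1,2,3
    assert res.bias == pytest.approx(2.0)
    assert res.sd == pytest.approx(1.0)
    assert res.lower_limit == pytest.approx(0.04)
    assert res.upper_limit == pytest.approx(3.96)
    means = [p[0] for p in res.points]
    assert means == pytest.approx([1.5, 3.0, 4.5])


def test_bland_altman_antisymmetric():
    rng = np.random.default_rng(4)
    a, b = rng.normal(500, 50, 30), rng.normal(480, 40, 30)
    ab, ba = bland_altman(a, b), bland_altman(b, a)
    assert ab.bias == pytest.approx(-ba.bias)
    assert ab.lower_limit == pytest.approx(-ba.upper_limit)
    assert ab.upper_limit == pytest.approx(-ba.lower_limit)


def test_bland_altman_normal_simulation_bounds():
    rng = np.random.default_rng(10)
    d = rng.normal(5.0, 10.0, 10_000)
    res = bland_altman(d, np.zeros_like(d))
    assert abs(res.bias - 5.0) < 0.3  # ~3·SE of the mean
    assert abs(res.lower_limit - (-14.6)) < 0.6
    assert abs(res.upper_limit - 24.6) < 0.6


def test_bland_altman_contracts():
    with pytest.raises(ValueError):
        bland_altman([1.0, 2.0], [1.0])
    with pytest.raises(ValueError):
        bland_altman([1.0], [1.0])


# -- Gage R&R ---------------------------------------------------------------


def _rr_table(part_sd=50.0, op_sd=10.0, rep_sd=5.0, p=10, o=2, r=3, seed=0):
    rng = np.random.default_rng(seed)
    parts = rng.normal(0, part_sd, p)
    ops = rng.normal(0, op_sd, o)
    rows = [
        (i, j, k, parts[i] + ops[j] + rng.normal(0, rep_sd))
        for i in range(p) for j in range(o) for k in range(r)
    ]
    return pd.DataFrame(rows, columns=["part", "operator", "replicate", "measurement"])


def test_zero_operator_variance_gives_zero_contribution():
    df = _rr_table(op_sd=0.0, rep_sd=0.0)
    df["measurement"] = df["part"] * 7.0  # depends on part only
    res = gage_rr(df)
    assert res.operator_contribution_pct == 0.0
    assert res.pct_part == pytest.approx(100.0)


def test_contributions_sum_to_100_and_nonnegative():
    res = gage_rr(_rr_table(seed=5))
    total = res.pct_part + res.pct_operator + res.pct_interaction + res.pct_repeatability
    assert total == pytest.approx(100.0, abs=1e-9)
    for v in (res.var_part, res.var_operator, res.var_interaction, res.var_repeatability):
        assert v >= 0.0


def test_contribution_invariant_to_shift_and_scale():
    df = _rr_table(seed=8)
    base = gage_rr(df)
    shifted = df.assign(measurement=df["measurement"] + 1234.5)
    scaled = df.assign(measurement=df["measurement"] * 3.7)
    assert gage_rr(shifted).operator_contribution_pct == pytest.approx(
        base.operator_contribution_pct, abs=1e-9
    )
    assert gage_rr(scaled).operator_contribution_pct == pytest.approx(
        base.operator_contribution_pct, abs=1e-9
    )


def test_design_contracts():
    df = _rr_table()
    with pytest.raises(ValueError, match="operators"):
        gage_rr(df[df["operator"] == 0])
    with pytest.raises(ValueError, match="unbalanced"):
        gage_rr(df.iloc[:-1])
    with pytest.raises(ValueError, match="replicates"):
        gage_rr(df[df["replicate"] == 0])


# -- sensitivity / specificity ----------------------------------------------


def test_four_classification_branches():
    res = classify_cohort(
        [("a", True, 106.0), ("b", True, 104.0), ("c", False, 106.0), ("d", False, 104.0)],
        reference=100.0,
    )
    assert res.classes == {"a": "TP", "b": "FN", "c": "FP", "d": "TN"}


def test_boundary_exactly_five_percent_is_negative():
    """'over 5%' is strict: a deviation of exactly 5% classifies negative."""
    res = classify_cohort([("p", True, 105.0), ("c", False, 95.0)], reference=100.0)
    assert res.classes == {"p": "FN", "c": "TN"}


def test_sensitivity_specificity_arithmetic():
    records = (
        [(f"tp{i}", True, 120.0) for i in range(3)]
        + [("fn0", True, 101.0)]
        + [(f"tn{i}", False, 100.0) for i in range(4)]
        + [("fp0", False, 120.0)]
    )
    res = classify_cohort(records, reference=100.0)
    assert res.counts == {"TP": 3, "FN": 1, "FP": 1, "TN": 4}
    assert res.sensitivity_pct == pytest.approx(75.0)
    assert res.specificity_pct == pytest.approx(80.0)


def test_separable_cohort_fully_sensitive_and_specific():
    """7 pathologic scans all deviating >5% and 2 controls within 5%."""
    records = [(f"p{i}", True, 130.0 + i) for i in range(7)]
    records += [("c0", False, 99.0), ("c1", False, 101.0)]
    res = classify_cohort(records, reference="auto")
    assert res.reference_mm3 == pytest.approx(100.0)
    assert res.sensitivity_pct == 100.0 and res.specificity_pct == 100.0


def test_auto_reference_requires_controls():
    with pytest.raises(ValueError, match="non-pathologic"):
        classify_cohort([("p", True, 100.0)], reference="auto")


@given(th=st.floats(0.0, 50.0))
def test_positivity_monotone_in_threshold(th):
    records = [(f"s{i}", True, v) for i, v in enumerate([100.0, 103.0, 110.0, 140.0])]
    loose = classify_cohort(records, reference=100.0, threshold_pct=th)
    tighter = classify_cohort(records, reference=100.0, threshold_pct=th + 5.0)
    n_pos = lambda r: sum(c == "TP" for c in r.classes.values())  # noqa: E731
    assert n_pos(tighter) <= n_pos(loose)
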