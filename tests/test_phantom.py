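"""Synthetic thorax and calibration phantoms: truth-manifest consistency."""

from dataclasses import replace

import numpy as np
import pytest

from conelung import (
    CohortPopulation,
    PhantomSpec,
    fit_lung_regression,
    generate_calibration_phantom,
    generate_cohort,
    generate_thorax_phantom,
    measure_thorax,
)
from conftest import SMALL_SPEC

SMALL_POP = CohortPopulation(shape=(112, 128, 152), spacing=(0.15, 0.15, 0.15))


def test_manifest_volumes_equal_mask_counts(healthy_phantom):
    truth, masks = healthy_phantom.truth, healthy_phantom.masks
    voxvol = masks["cavity"].voxel_volume_mm3
    assert truth.thoracic_volume_mm3 == pytest.approx(int(masks["cavity"].data.sum()) * voxvol)
    assert truth.lung_volume_mm3 == pytest.approx(int(masks["lung"].data.sum()) * voxvol)
    assert truth.aerated_volume_mm3 == pytest.approx(int(masks["aerated"].data.sum()) * voxvol)
    assert truth.aerated_volume_mm3 <= truth.lung_volume_mm3 <= truth.thoracic_volume_mm3


def test_same_seed_bit_identical():
    a = generate_thorax_phantom(SMALL_SPEC)
    b = generate_thorax_phantom(SMALL_SPEC)
    assert np.array_equal(a.volume.data, b.volume.data)
    assert a.truth == b.truth


def test_full_aeration_means_aerated_equals_lung():
    ph = generate_thorax_phantom(replace(SMALL_SPEC, aeration_fraction=1.0), render=False)
    assert ph.truth.aerated_volume_mm3 == pytest.approx(ph.truth.lung_volume_mm3)


def test_consolidation_burden_reduces_aerated_volume(pathologic_phantom):
    """Burden 0.3 on a fully aerated lung leaves 70% aerated (±1 voxel)."""
    truth = pathologic_phantom.truth
    voxvol = pathologic_phantom.masks["lung"].voxel_volume_mm3
    assert truth.pathologic
    assert abs(truth.aerated_volume_mm3 - 0.7 * truth.lung_volume_mm3) <= voxvol


def test_intensity_model(healthy_phantom):
    """Tissue compartments land in their HU classes (zero-noise phantom)."""
    vol = healthy_phantom.volume.data
    masks = healthy_phantom.masks
    aer = vol[masks["aerated"].data]
    assert aer.min() > -700 and aer.max() < -300
    assert abs(np.median(aer) - (-500)) < 30
    assert vol[0, 0, 0] == -1000  # background air
    body_only = masks["body"].data & ~masks["cavity"].data
    assert (vol[body_only] >= 400).any()  # bone present in the body wall
    assert np.median(vol[body_only]) == pytest.approx(40, abs=15)


def test_landmarks_match_spec_geometry(healthy_phantom):
    m = measure_thorax(healthy_phantom.truth.landmarks)
    assert m.d_small == pytest.approx(6.0, abs=1e-9)
    assert m.d_large == pytest.approx(7.6, abs=1e-9)
    assert m.height == pytest.approx(9.0, abs=1e-9)
    rib = np.asarray(healthy_phantom.truth.rib_small_base)
    assert np.linalg.norm(rib[0] - rib[1]) > m.d_small  # rib fallback spans wider


def test_ratio_monotone_in_lung_fraction():
    lo = generate_thorax_phantom(replace(SMALL_SPEC, lung_fraction=0.5), render=False)
    hi = generate_thorax_phantom(replace(SMALL_SPEC, lung_fraction=0.7), render=False)
    assert (
        hi.truth.lung_volume_mm3 / hi.truth.thoracic_volume_mm3
        > lo.truth.lung_volume_mm3 / lo.truth.thoracic_volume_mm3
    )


def test_spec_validation():
    with pytest.raises(ValueError):
        PhantomSpec(lung_fraction=1.4)
    with pytest.raises(ValueError):
        PhantomSpec(pathology="nodules", burden_fraction=0.95, aeration_fraction=0.9)
    with pytest.raises(ValueError):
        PhantomSpec(pathology="emphysema")
    with pytest.raises(ValueError, match="fit"):
        generate_thorax_phantom(replace(SMALL_SPEC, height_mm=30.0), render=False)
    with pytest.raises(ValueError, match="infeasible"):
        generate_thorax_phantom(replace(SMALL_SPEC, lung_fraction=0.99), render=False)


# -- calibration tube -------------------------------------------------------


def test_calibration_phantom_designed_means_exact():
    vol, air, water = generate_calibration_phantom(noise_sd=0.0)
    assert float(vol.data[air.data].mean()) == 10000.0
    assert float(vol.data[water.data].mean()) == 30000.0


def test_calibration_vois_disjoint_and_large():
    _, air, water = generate_calibration_phantom()
    assert not (air.data & water.data).any()
    assert air.data.sum() >= 10_000 and water.data.sum() >= 10_000


def test_calibration_phantom_noisy_means_within_3_grey():
    vol, air, water = generate_calibration_phantom(noise_sd=50.0, seed=21)
    assert abs(float(vol.data[air.data].mean()) - 10000.0) < 3.0
    assert abs(float(vol.data[water.data].mean()) - 30000.0) < 3.0


def test_calibration_phantom_too_small_grid():
    with pytest.raises(ValueError):
        generate_calibration_phantom(shape=(10, 16, 16))


# -- cohorts ----------------------------------------------------------------


def test_noiseless_cohort_recovers_line_exactly():
    cohort = generate_cohort(5, population=SMALL_POP, noise_sd=0.0, seed=3,
                             render_volumes=False)
    pairs = [(p.truth.thoracic_volume_mm3, p.truth.lung_volume_mm3) for p in cohort]
    model = fit_lung_regression(pairs)
    # exact up to one-voxel rounding of the lung target
    assert model.slope == pytest.approx(0.20, abs=1e-4)
    assert model.intercept == pytest.approx(300.0, abs=0.1)
    assert model.r_squared > 1 - 1e-6


def test_cohort_requires_three():
    with pytest.raises(ValueError, match=">= 3"):
        generate_cohort(2)


def test_cohort_infeasible_line():
    with pytest.raises(ValueError, match="infeasible"):
        generate_cohort(3, population=SMALL_POP, slope=0.9, intercept=500.0, seed=0,
                        render_volumes=False)


def test_frustum_correlates_with_cavity_truth(regression_cohort):
    """The landmark frustum tracks the true cavity volume across a cohort."""
    from conelung import truncated_cone_volume

    frustum = [truncated_cone_volume(measure_thorax(p.truth.landmarks)) for p in regression_cohort]
    cavity = [p.truth.thoracic_volume_mm3 for p in regression_cohort]
    r2 = np.corrcoef(frustum, cavity)[0, 1] ** 2
    assert r2 > 0.6
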