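"""Threshold segmentation, contour delineation and mask volumetry."""

import numpy as np
import pytest

from conelung import (
    CTVolume,
    HUWindow,
    VOIMask,
    delineate_from_contours,
    mask_volume_mm3,
    threshold_segment,
)
from conelung.segmentation import (
    WINDOW_ALTERNATE,
    WINDOW_REFERENCE,
    SliceContourSet,
    contours_from_mask,
)


def _toy_body():
    """Soft-tissue body containing a 10³ aerated cube at −350 HU."""
    data = np.full((40, 40, 40), 40.0, dtype=np.float32)
    data[:2] = -1000.0  # exterior air touching the border
    data[15:25, 15:25, 15:25] = -350.0
    data[30, 30, 30] = -700.0  # single in-window voxel: below min component size
    return CTVolume(data, spacing=(0.05,) * 3, units="HU")


def test_uniform_cube_volume():
    vol = _toy_body()
    mask = threshold_segment(vol, WINDOW_REFERENCE)
    assert int(mask.data.sum()) == 1000
    assert mask_volume_mm3(mask) == pytest.approx(1000 * 0.05**3)


def test_window_edges_inclusive_and_air_excluded():
    vol = _toy_body()
    vol.data[15, 15, 15] = -700.0  # exactly at the floor, inside the cube
    vol.data[15, 15, 16] = -300.0  # exactly at the ceiling
    vol.data[15, 15, 17] = -1000.0  # pure air: excluded
    mask = threshold_segment(vol, WINDOW_REFERENCE)
    assert mask.data[15, 15, 15] and mask.data[15, 15, 16]
    assert not mask.data[15, 15, 17]


def test_border_components_and_specks_removed():
    vol = _toy_body()
    vol.data[:2] = -500.0  # exterior air now inside the window but border-touching
    mask = threshold_segment(vol, WINDOW_REFERENCE)
    assert not mask.data[:2].any()
    assert not mask.data[30, 30, 30]  # isolated speck < 27 voxels


def test_empty_window_errors():
    vol = CTVolume(np.full((8, 8, 8), 40.0, dtype=np.float32), (0.05,) * 3, units="HU")
    with pytest.raises(ValueError, match="check calibration"):
        threshold_segment(vol, WINDOW_REFERENCE)


def test_requires_hu_units():
    vol = CTVolume(np.full((8, 8, 8), 100, dtype=np.int32), (0.05,) * 3)
    with pytest.raises(ValueError, match="HU"):
        threshold_segment(vol, WINDOW_REFERENCE)


def test_threshold_recovers_phantom_aerated_truth(healthy_phantom):
    mask = threshold_segment(healthy_phantom.volume, WINDOW_REFERENCE)
    truth = healthy_phantom.truth.aerated_volume_mm3
    assert abs(mask_volume_mm3(mask) - truth) / truth < 0.02


def test_window_widening_never_shrinks_mask(healthy_phantom, noisy_phantom):
    for ph in (healthy_phantom, noisy_phantom):
        narrow = threshold_segment(ph.volume, WINDOW_ALTERNATE)
        wide = threshold_segment(ph.volume, WINDOW_REFERENCE)
        assert not (narrow.data & ~wide.data).any()  # exact subset


def test_pathologic_threshold_below_delineation(pathologic_phantom):
    """Lesions leave the HU window but stay inside drawn lung contours."""
    thr = threshold_segment(pathologic_phantom.volume, WINDOW_REFERENCE)
    contours = contours_from_mask(pathologic_phantom.masks["lung"], every=2)
    manual = delineate_from_contours(contours, pathologic_phantom.volume)
    assert mask_volume_mm3(thr) < mask_volume_mm3(manual)


# -- contour delineation ----------------------------------------------------


def _sphere_contours(every, radius=2.0, spacing=0.05, n=96, vertices=128):
    grid = CTVolume(np.zeros((n, n, n), dtype=np.float32), (spacing,) * 3, units="HU")
    c = (n - 1) / 2 * spacing
    theta = np.linspace(0.0, 2.0 * np.pi, vertices + 1)[:-1]
    contours = {}
    for k in range(0, n, every):
        dz = k * spacing - c
        if abs(dz) >= radius:
            continue
        r = np.sqrt(radius**2 - dz**2)
        poly = np.stack([c + r * np.cos(theta), c + r * np.sin(theta)], axis=1)
        contours[k] = [poly]
    return grid, SliceContourSet(contours)


def test_sphere_interpolated_volume():
    """2 mm sphere annotated on every 2nd slice → 4/3·π·2³ within 2%."""
    grid, contours = _sphere_contours(every=2)
    vol = mask_volume_mm3(delineate_from_contours(contours, grid))
    analytic = 4.0 / 3.0 * np.pi * 2.0**3
    assert abs(vol - analytic) / analytic < 0.02


def test_refining_annotation_changes_volume_below_1pct():
    grid, coarse = _sphere_contours(every=2)
    _, fine = _sphere_contours(every=1)
    v_coarse = mask_volume_mm3(delineate_from_contours(coarse, grid))
    v_fine = mask_volume_mm3(delineate_from_contours(fine, grid))
    assert abs(v_coarse - v_fine) / v_fine < 0.01


def test_fully_annotated_equals_per_slice_rasterization():
    grid, fine = _sphere_contours(every=1)
    mask = delineate_from_contours(fine, grid)
    annotated = set(fine.contours)
    for k in range(grid.shape[0]):
        if k not in annotated:
            assert not mask.data[k].any()


def test_no_mask_outside_annotated_extent():
    square = np.array([[1.0, 1.0], [1.0, 3.0], [3.0, 3.0], [3.0, 1.0]])
    grid = CTVolume(np.zeros((30, 90, 90), dtype=np.float32), (0.05,) * 3, units="HU")
    contours = SliceContourSet({10: [square], 20: [square]})
    mask = delineate_from_contours(contours, grid)
    assert mask.data[10:21].any()
    assert not mask.data[:10].any() and not mask.data[21:].any()  # e.g. slice 25 empty


def test_contour_validation():
    square = np.array([[1.0, 1.0], [1.0, 3.0], [3.0, 3.0], [3.0, 1.0]])
    with pytest.raises(ValueError, match=">= 2 annotated"):
        SliceContourSet({10: [square]})
    grid = CTVolume(np.zeros((30, 20, 20), dtype=np.float32), (0.05,) * 3, units="HU")
    with pytest.raises(ValueError, match="out of bounds"):
        delineate_from_contours(SliceContourSet({5: [square], 9: [square]}), grid)


def test_even_odd_fill_cuts_holes():
    outer = np.array([[0.5, 0.5], [0.5, 4.0], [4.0, 4.0], [4.0, 0.5]])
    inner = np.array([[1.5, 1.5], [1.5, 3.0], [3.0, 3.0], [3.0, 1.5]])
    grid = CTVolume(np.zeros((6, 100, 100), dtype=np.float32), (0.05,) * 3, units="HU")
    mask = delineate_from_contours(SliceContourSet({1: [outer, inner], 3: [outer, inner]}), grid)
    assert mask.data[1, 60, 60] == False  # noqa: E712 - inside the hole
    assert mask.data[1, 25, 25]


# -- volumetry --------------------------------------------------------------


def test_mask_volume_closed_forms(healthy_phantom):
    empty = VOIMask(np.zeros((4, 4, 4), dtype=bool), (0.05,) * 3)
    assert mask_volume_mm3(empty) == 0.0
    cube = VOIMask(np.ones((20, 20, 20), dtype=bool), (0.05,) * 3)
    assert mask_volume_mm3(cube) == pytest.approx(1.0)  # 8000 × 1.25e-4
    lung = healthy_phantom.masks["lung"]
    assert mask_volume_mm3(lung) == pytest.approx(healthy_phantom.truth.lung_volume_mm3)


def test_window_validation():
    with pytest.raises(ValueError):
        HUWindow(-300, -700)
    assert HUWindow.parse("-700:-300") == WINDOW_REFERENCE
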