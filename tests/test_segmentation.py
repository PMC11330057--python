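"""Contrast transforms, thresholding, contact-adjacent component selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from swirseg import (
    IntensityImage,
    Modality,
    PhantomConfig,
    RoiSet,
    calibrate_px_to_mm,
    contrast_map,
    lesion_metrics,
    make_swir_phantom,
    segment_lesion,
    select_lesion,
    threshold_mask,
)
from swirseg.segmentation import ContrastMap
from swirseg.pipeline import default_swir_rois


def _tiny(values, modality):
    """A small frame whose first row is the sound region."""
    arr = np.asarray(values, dtype=float)
    img = IntensityImage(arr, modality)
    sound = np.column_stack([np.zeros(arr.shape[1], int), np.arange(arr.shape[1])])
    contact = np.array([[arr.shape[0] - 1, 0]])
    return img, RoiSet(sound_region=sound, contact_roi=contact)


def test_reflectance_contrast_arithmetic():
    img, roi = _tiny([[100.0, 100.0], [125.0, 100.0]], Modality.REFLECTANCE)
    cm = contrast_map(img, roi)
    assert cm.i_s == 100.0
    assert cm.values[1, 0] == pytest.approx((125 - 100) / 125)  # 0.2
    assert cm.values[1, 1] == 0.0


def test_transillumination_contrast_arithmetic():
    img, roi = _tiny([[100.0, 100.0], [100.0, 73.0]], Modality.PROXIMAL_TRANS)
    cm = contrast_map(img, roi)
    assert cm.values[1, 0] == 0.0  # identity case
    assert cm.values[1, 1] == pytest.approx(0.27)


def test_reflectance_zero_pixel_is_flagged_invalid():
    img, roi = _tiny([[100.0, 100.0], [0.0, 50.0]], Modality.REFLECTANCE)
    cm = contrast_map(img, roi)
    assert not cm.valid[1, 0]
    assert not threshold_mask(cm)[1, 0]


def test_contrast_map_rejects_zero_sound_reference():
    img, roi = _tiny([[0.0, 0.0], [1.0, 1.0]], Modality.REFLECTANCE)
    with pytest.raises(ValueError, match="positive"):
        contrast_map(img, roi)


def test_threshold_boundary_pixel_is_kept():
    """Only contrast strictly below the threshold is removed."""
    cm = ContrastMap(values=np.array([[0.0, 0.1, 0.0999]]), i_s=1.0,
                     modality=Modality.REFLECTANCE,
                     valid=np.ones((1, 3), bool))
    mask = threshold_mask(cm, 0.1)
    assert mask.tolist() == [[False, True, False]]
    assert not threshold_mask(
        ContrastMap(np.zeros((2, 2)), 1.0, Modality.REFLECTANCE,
                    np.ones((2, 2), bool))
    ).any()


@settings(max_examples=50, derandomize=True)
@given(st.integers(0, 2**32 - 1), st.floats(0.05, 0.5), st.floats(0.0, 0.4))
def test_raising_threshold_never_enlarges_mask(seed, t1, dt):
    values = np.random.default_rng(seed).normal(0.1, 0.2, (16, 16))
    cm = ContrastMap(values, 1.0, Modality.REFLECTANCE, np.ones((16, 16), bool))
    low, high = threshold_mask(cm, t1), threshold_mask(cm, t1 + dt)
    assert not (high & ~low).any()


def test_select_lesion_keeps_only_contact_adjoining_blob():
    mask = np.zeros((20, 20), bool)
    mask[8:12, 10:14] = True     # adjoins the contact column
    mask[2:5, 2:5] = True        # distant specular blob
    roi = RoiSet(sound_region=np.array([[0, 0]]),
                 contact_roi=np.column_stack([np.arange(20), np.full(20, 9)]))
    seg = select_lesion(mask, roi)
    assert seg.detected and seg.area_px == 16
    assert not seg.mask[2:5, 2:5].any()


def test_select_lesion_empty_mask_is_negative():
    roi = RoiSet(sound_region=np.array([[0, 0]]), contact_roi=np.array([[5, 5]]))
    seg = select_lesion(np.zeros((10, 10), bool), roi)
    assert not seg.detected and seg.area_px == 0


def test_diagonal_adjacency_counts_with_8_connectivity():
    mask = np.zeros((10, 10), bool)
    mask[5, 5] = True
    roi = RoiSet(sound_region=np.array([[0, 0]]), contact_roi=np.array([[4, 4]]))
    assert select_lesion(mask, roi, connectivity=2).detected
    assert not select_lesion(mask, roi, connectivity=1).detected


@pytest.mark.parametrize("c_true,expected_rate", [(0.2, 1.0), (0.05, 0.0)])
def test_detection_rate_over_seeded_phantoms(c_true, expected_rate):
    """Noise-free phantoms: c = 0.2 always segments, c = 0.05 never does."""
    hits = 0
    for seed in range(50):
        cfg = PhantomConfig(lesion_contrast_true=c_true, noise_sigma=0.0,
                            seed=seed)
        frame, _ = make_swir_phantom(cfg)
        _, seg = segment_lesion(frame, default_swir_rois(cfg))
        hits += seg.detected
    assert hits / 50 == expected_rate


def test_lesion_metrics_on_square_mask():
    """3x3 square of contrast 0.2 with a vertical contact along one edge."""
    mask = np.zeros((9, 9), bool)
    mask[3:6, 4:7] = True
    cm = ContrastMap(np.full((9, 9), 0.2), 1.0, Modality.REFLECTANCE,
                     np.ones((9, 9), bool))
    roi = RoiSet(sound_region=np.array([[0, 0]]),
                 contact_roi=np.column_stack([np.arange(9), np.full(9, 4)]))
    seg = select_lesion(mask, roi)
    seg = lesion_metrics(seg, cm, roi, mm_per_pixel=0.1)
    assert seg.area_px == 9
    assert seg.mean_contrast == pytest.approx(0.2)
    assert seg.depth_mm == pytest.approx(0.3)
    assert seg.area_mm2 == pytest.approx(9 * 0.01)


def test_metrics_without_scale_warns_and_stays_in_pixels():
    mask = np.zeros((5, 5), bool)
    mask[2, 2] = True
    cm = ContrastMap(np.full((5, 5), 0.3), 1.0, Modality.REFLECTANCE,
                     np.ones((5, 5), bool))
    roi = RoiSet(sound_region=np.array([[0, 0]]), contact_roi=np.array([[2, 1]]))
    seg = select_lesion(mask, roi)
    with pytest.warns(UserWarning, match="pixels only"):
        seg = lesion_metrics(seg, cm, roi, mm_per_pixel=None)
    assert seg.depth_px == 1.0 and seg.depth_mm is None


def test_artifacts_away_from_contact_do_not_change_metrics():
    base = dict(lesion_contrast_true=0.2, noise_sigma=0.0)
    cfg_clean = PhantomConfig(specular_spots=[], **base)
    cfg_spots = PhantomConfig(
        specular_spots=[((28, 36), 9, 0.95), ((160, 40), 7, 0.9)], **base)
    roi = default_swir_rois(cfg_clean)
    results = []
    for cfg in (cfg_clean, cfg_spots):
        frame, _ = make_swir_phantom(cfg)
        _, seg = segment_lesion(frame, roi)
        results.append((seg.detected, seg.area_px, seg.mean_contrast))
    assert results[0] == results[1]


def _flood_fill_components(mask):
    """Brute-force 8-connected labeling by BFS; independent of skimage."""
    comps, seen = [], set()
    coords = {tuple(p) for p in np.argwhere(mask)}
    for start in sorted(coords):
        if start in seen:
            continue
        comp, queue = set(), [start]
        seen.add(start)
        while queue:
            r, c = queue.pop()
            comp.add((r, c))
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    nb = (r + dr, c + dc)
                    if nb in coords and nb not in seen:
                        seen.add(nb)
                        queue.append(nb)
        comps.append(comp)
    return comps


def test_component_selection_matches_flood_fill_oracle():
    rng = np.random.default_rng(20240817)
    contact_col = 16
    roi = RoiSet(sound_region=np.array([[0, 0]]),
                 contact_roi=np.column_stack(
                     [np.arange(32), np.full(32, contact_col)]))
    contact = set(map(tuple, roi.contact_roi))
    near = {(r + dr, c + dc) for r, c in contact
            for dr in (-1, 0, 1) for dc in (-1, 0, 1)}
    for _ in range(1000):
        mask = rng.random((32, 32)) < rng.uniform(0.05, 0.45)
        mask[:, contact_col] &= rng.random(32) < 0.5
        expected = set()
        for comp in _flood_fill_components(mask):
            if comp & near:
                expected |= comp
        seg = select_lesion(mask, roi)
        assert set(map(tuple, np.argwhere(seg.mask))) == expected


def test_calibration():
    img = IntensityImage(np.ones((4, 4)), Modality.REFLECTANCE)
    assert calibrate_px_to_mm(img, 10.0, 200.0).mm_per_pixel == pytest.approx(0.05)
    with pytest.raises(ValueError):
        calibrate_px_to_mm(img, 10.0, 0.0)
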