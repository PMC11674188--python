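"""Automated fascia / bone delineation."""

import itertools

import numpy as np
import pytest
from scipy import ndimage as ndi

from imfseg.roi import (
    BoneMask,
    RoiConfig,
    delineate_roi,
    final_roi,
    mask_to_contour,
    refine_fascia,
    remove_overshoot,
    seed_muscle_mask,
    tissue_premask,
)
from imfseg.types import ImageVolume


def _multiotsu_bruteforce(values, classes=3):
    """Exhaustive between-class variance maximization over threshold pairs."""
    hist, edges = np.histogram(values, bins=128)
    centers = (edges[:-1] + edges[1:]) / 2
    p = hist / hist.sum()
    best, best_t = -1.0, None
    for i, j in itertools.combinations(range(1, len(centers) - 1), 2):
        segs = [(0, i), (i, j), (j, len(centers))]
        var = 0.0
        ok = True
        for a, b in segs:
            w = p[a:b].sum()
            if w == 0:
                ok = False
                break
            mu = (p[a:b] * centers[a:b]).sum() / w
            var += w * mu**2
        if ok and var > best:
            best, best_t = var, (centers[i - 1 : i + 1].mean(), centers[j - 1 : j + 1].mean())
    return best_t


def test_premask_thresholds_fall_in_histogram_valleys(rng):
    """Trimodal image: thresholds land between the three modes."""
    vals = np.concatenate(
        [rng.normal(10, 3, 4000), rng.normal(100, 8, 4000), rng.normal(220, 10, 2000)]
    )
    img = np.clip(vals, 0, None).reshape(100, 100)
    pm = tissue_premask(img)
    assert set(np.unique(pm)) == {0, 1, 2}
    # class means straddle the generating modes
    assert img[pm == 0].mean() < 50 < img[pm == 1].mean() < 160 < img[pm == 2].mean()
    # thresholds agree with a brute-force between-class-variance search
    t_low = (img[pm == 0].max() + img[pm == 1].min()) / 2
    t_high = (img[pm == 1].max() + img[pm == 2].min()) / 2
    bf = _multiotsu_bruteforce(img.ravel())
    assert abs(t_low - bf[0]) < 25 and abs(t_high - bf[1]) < 25


def test_premask_bimodal_high_class():
    img = np.concatenate([np.full(50, 10.0), np.full(50, 200.0)]).reshape(10, 10)
    pm = tissue_premask(img)
    assert (pm[img == 200.0] == 2).all()


def test_premask_constant_image_degrades():
    pm = tissue_premask(np.full((8, 8), 7.0))
    assert pm.shape == (8, 8)


def test_premask_fat_class_covers_subcutaneous(calf_phantom, calf_case):
    """The fat-like class captures at least 95% of true subcutaneous fat."""
    subq_true = calf_phantom.labels.mask("subcutaneous_fat")
    fat_class = calf_case.roi.premask == 2
    assert (fat_class & subq_true).sum() / subq_true.sum() >= 0.95


def test_bone_recovered_without_touching_muscle(calf_phantom, calf_case):
    bone = calf_case.roi.bone
    true_bone = calf_phantom.labels.mask("bone")
    true_muscle = calf_phantom.labels.mask("muscle")
    assert bone.found
    assert (bone.mask & true_bone).sum() / true_bone.sum() >= 0.95
    assert (bone.mask & true_muscle).sum() / max(bone.mask.sum(), 1) < 0.02


def test_cortex_boundary_tie_kept():
    """A low-signal object of exactly the minimum area is retained (>= rule)."""
    from imfseg.roi import segment_bone

    vol = ImageVolume(
        data=np.full((2, 60, 60), 100.0), spacing_yx=(1.0, 1.0), slice_thickness=2.0
    )
    low = np.zeros((2, 60, 60), dtype=bool)
    # 234 px at 1 mm pixels = exactly 234 mm^2, away from the border
    block = np.zeros((60, 60), dtype=bool)
    block[20:33, 20:38] = True  # 13*18 = 234
    low[0] = block
    fat = np.zeros_like(low)
    bone = segment_bone(vol, fat, low, RoiConfig())
    assert bone.found and bone.mask[0][block].all()


def test_bone_absent_flagged():
    from imfseg.roi import segment_bone

    vol = ImageVolume(data=np.full((2, 32, 32), 100.0), spacing_yx=(1.0, 1.0), slice_thickness=2.0)
    bone = segment_bone(vol, np.zeros(vol.shape, bool), np.zeros(vol.shape, bool), RoiConfig())
    assert not bone.found and not bone.mask.any()


def test_seed_contour_encloses_muscle_compartment(calf_phantom, calf_case, pipeline_config):
    from imfseg.preprocess import clahe_correct

    pre = clahe_correct(calf_phantom.volume, pipeline_config.preprocess)
    z = 5
    seed = seed_muscle_mask(calf_case.roi.premask[z], calf_phantom.volume, pipeline_config.roi)
    comp = calf_phantom.compartment_mask[z]
    assert (seed & comp).sum() / comp.sum() >= 0.98


def test_hole_smaller_than_cap_is_closed():
    cfg = RoiConfig(small_object_max_cm2=0.02, hole_max_cm2=0.6, closing_radius_mm=1.0)
    vol = ImageVolume(data=np.zeros((1, 60, 60)), spacing_yx=(1.0, 1.0), slice_thickness=1.0)
    pm = np.zeros((60, 60), dtype=np.uint8)
    pm[10:50, 10:50] = 1
    pm[25:30, 25:30] = 2  # a 25 mm^2 "fat streak" hole (< 60 mm^2 cap)
    seed = seed_muscle_mask(pm, vol, cfg)
    assert seed[26, 26]  # hole filled
    assert seed[12:48, 12:48].all()  # interior intact (opening rounds corners)
    # a hole above the cap stays open
    cfg2 = RoiConfig(small_object_max_cm2=0.02, hole_max_cm2=0.002, closing_radius_mm=1.0)
    seed2 = seed_muscle_mask(pm, vol, cfg2)
    assert not seed2[27, 27]


def test_convex_hull_increases_concave_seed_area(rng):
    """A concave (muscle-edge-following) seed strictly grows under the hull,
    and the snake holds the hull against a real boundary edge."""
    from skimage import morphology

    seed = np.zeros((80, 80), dtype=bool)
    seed[20:60, 20:60] = True
    seed[20:45, 35:45] = False  # carve a notch -> concave
    hull = morphology.convex_hull_image(seed)
    assert hull.sum() > seed.sum() and hull[seed].all()
    # image with a true edge at the square outline: dark outside, tissue inside
    img = np.full((80, 80), 20.0)
    img[20:60, 20:60] = 100.0
    img += rng.normal(0, 1, (80, 80))
    refined = refine_fascia(seed, img, RoiConfig())
    assert refined.sum() > seed.sum()
    assert refined[seed].mean() > 0.95  # snake keeps (almost all of) the seed


def test_snake_moves_little_on_already_convex_boundary(calf_phantom, calf_case, pipeline_config):
    """On an elliptical fascia the hull is the answer; snakes refine <= a
    couple of pixels of boundary."""
    z = 5
    from skimage import morphology

    roi_slice = calf_case.roi.muscle_mask[z] | calf_case.roi.bone.mask[z]
    comp = calf_phantom.compartment_mask[z] | (calf_phantom.labels.mask("bone")[z])
    sym_diff = roi_slice ^ ndi.binary_fill_holes(comp)
    # disagreement confined to a thin boundary band
    eroded = morphology.binary_erosion(ndi.binary_fill_holes(comp), morphology.disk(3))
    assert not (sym_diff & eroded).any()


def test_overshoot_wedge_removed_with_z_support():
    """A bright wedge touching the bone across 5 slices is removed on all 5;
    an unsupported single-slice speck is retained."""
    nz, ny, nx = 7, 60, 60
    data = np.full((nz, ny, nx), 100.0)
    muscle = np.zeros((nz, ny, nx), dtype=bool)
    muscle[:, 5:55, 5:55] = True
    bone = np.zeros_like(muscle)
    bone[:, 25:35, 25:35] = True
    data[bone] = 5.0
    # wedge of "subcutaneous" fat abutting the bone on slices 1..5
    wedge = np.zeros_like(muscle)
    wedge[1:6, 35:45, 25:35] = True
    data[wedge] = 220.0
    # single-slice bright speck touching bone, no z neighbours
    speck = np.zeros_like(muscle)
    speck[0, 22:24, 22:24] = True
    data[speck] = 220.0
    vol = ImageVolume(data=data, spacing_yx=(1.0, 1.0), slice_thickness=2.0)
    bm = BoneMask(mask=bone, primary=bone, n_bones=1, found=True)
    cfg = RoiConfig(overshoot_min_area_mm2=4.0)
    out = remove_overshoot(muscle, bm, vol, cfg)
    assert not (out & wedge).any()  # wedge gone on all 5 slices
    assert (out & speck).sum() == speck.sum()  # 3-D fidelity exception


def test_overshoot_requires_bone_contact():
    nz, ny, nx = 4, 40, 40
    data = np.full((nz, ny, nx), 100.0)
    muscle = np.ones((nz, ny, nx), dtype=bool)
    bone = np.zeros_like(muscle)
    bone[:, 2:6, 2:6] = True
    fat = np.zeros_like(muscle)
    fat[:, 25:33, 25:33] = True  # far from bone
    data[fat] = 220.0
    vol = ImageVolume(data=data, spacing_yx=(1.0, 1.0), slice_thickness=2.0)
    bm = BoneMask(mask=bone, primary=bone, n_bones=1, found=True)
    out = remove_overshoot(muscle, bm, vol, RoiConfig(overshoot_min_area_mm2=4.0))
    np.testing.assert_array_equal(out, muscle)


def test_final_roi_set_arithmetic(rng):
    vol = ImageVolume(data=rng.uniform(1, 10, (2, 20, 20)), spacing_yx=(1.0, 1.0), slice_thickness=1.0)
    muscle = np.zeros(vol.shape, dtype=bool)
    muscle[:, 2:18, 2:18] = True
    bone = np.zeros_like(muscle)
    bone[:, 5:9, 5:9] = True
    bm = BoneMask(mask=bone, primary=bone, n_bones=1, found=True)
    img, roi = final_roi(muscle, bm, vol)
    assert roi.sum() == muscle.sum() - (muscle & bone).sum()
    assert not (roi & bone).any()
    assert (img.data[~roi] == 0).all()
    # empty bone: ROI is the muscle mask unchanged
    none = BoneMask(mask=np.zeros_like(bone), primary=np.zeros_like(bone), n_bones=0, found=False)
    _, roi2 = final_roi(muscle, none, vol)
    np.testing.assert_array_equal(roi2, muscle)


def test_final_roi_empty_is_error(rng):
    vol = ImageVolume(data=rng.uniform(1, 10, (1, 8, 8)), spacing_yx=(1.0, 1.0), slice_thickness=1.0)
    empty = np.zeros(vol.shape, dtype=bool)
    bm = BoneMask(mask=empty, primary=empty, n_bones=0, found=False)
    with pytest.raises(ValueError):
        final_roi(empty, bm, vol)


def test_roi_excludes_subcutaneous_and_bone(calf_phantom, calf_case):
    roi = calf_case.roi.roi_mask
    subq = calf_phantom.labels.mask("subcutaneous_fat")
    bone_true = calf_phantom.labels.mask("bone")
    assert not (roi & calf_case.roi.bone.mask).any()  # exact, by construction
    assert (roi & subq).sum() / roi.sum() < 0.01
    assert (roi & bone_true).sum() / roi.sum() < 0.01


def test_roi_dice_against_truth(calf_phantom, calf_case):
    roi = calf_case.roi.roi_mask
    comp = calf_phantom.compartment_mask
    dice = 2 * (roi & comp).sum() / (roi.sum() + comp.sum())
    assert dice >= 0.95


def test_mask_to_contour_requires_nonempty():
    with pytest.raises(ValueError):
        mask_to_contour(np.zeros((5, 5), dtype=bool))
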