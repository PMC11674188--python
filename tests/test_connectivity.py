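"""Island reclassification rules and the brute-force 3-D oracle."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from imfseg.connectivity import CONNECTED, DEFINITE, NOISE, ConnectivityConfig, classify_islands


def _oracle_keep(mask: np.ndarray, pixel_area: float, min_area: float) -> np.ndarray:
    """Independent keep-mask: full 3-D 26-connected components.

    A voxel is kept iff its 3-D component either spans >= 2 slices or
    contains an in-plane island of area >= ``min_area``.
    """
    comp, n = ndi.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    keep = np.zeros_like(mask)
    min_px = int(np.ceil(min_area / pixel_area))
    for i in range(1, n + 1):
        m = comp == i
        zs = np.unique(np.where(m)[0])
        big = False
        for z in zs:
            lab2, k = ndi.label(m[z], structure=np.ones((3, 3), dtype=bool))
            if k and np.bincount(lab2.ravel())[1:].max() >= min_px:
                big = True
                break
        if len(zs) >= 2 or big:
            keep |= m
    return keep


def test_large_column_is_definite():
    """A thick column exceeding the area rule on every slice is definite fat."""
    mask = np.zeros((10, 30, 30), dtype=bool)
    mask[:, 5:10, 5:9] = True  # 20 px/slice at 1 mm pixels = 20 mm^2
    res = classify_islands(mask, (1.0, 1.0))
    assert (res.class_map[mask] == DEFINITE).all()
    np.testing.assert_array_equal(res.filtered, mask)


def test_isolated_speck_removed_as_noise():
    mask = np.zeros((10, 30, 30), dtype=bool)
    mask[5, 14, 14] = mask[5, 14, 15] = True
    res = classify_islands(mask, (1.0, 1.0))
    assert (res.class_map[mask] == NOISE).all()
    assert not res.filtered.any()


def test_small_island_with_z_support_retained():
    mask = np.zeros((10, 30, 30), dtype=bool)
    mask[6, 5:10, 5:9] = True  # definite island on slice 6
    mask[5, 6, 6] = mask[5, 6, 7] = mask[5, 7, 6] = True  # 3 px overlapping its footprint
    res = classify_islands(mask, (1.0, 1.0))
    assert (res.class_map[5][mask[5]] == CONNECTED).all()
    assert res.filtered[5].sum() == 3
    # cross-check with the independent 3-D component oracle
    np.testing.assert_array_equal(res.filtered, _oracle_keep(mask, 1.0, 16.0))


def test_single_slice_volume_uses_area_rule_only():
    mask = np.zeros((1, 30, 30), dtype=bool)
    mask[0, 2:7, 2:7] = True  # 25 mm^2 -> kept
    mask[0, 20, 20] = True  # 1 mm^2, no possible z-support -> removed
    res = classify_islands(mask, (1.0, 1.0))
    assert res.filtered[0, 3, 3] and not res.filtered[0, 20, 20]


def test_area_rule_respects_physical_units():
    """The same 3-voxel island passes at coarse pixels, fails at fine ones."""
    mask = np.zeros((1, 10, 10), dtype=bool)
    mask[0, 4, 4:7] = True
    coarse = classify_islands(mask, (3.0, 3.0))  # 27 mm^2
    fine = classify_islands(mask, (0.5, 0.5))  # 0.75 mm^2
    assert coarse.filtered.any() and not fine.filtered.any()


@pytest.mark.parametrize("trial", range(100))
def test_matches_bruteforce_oracle_on_random_masks(trial):
    """Zero voxel disagreement with the 3-D connected-component oracle on
    random sparse 32-cubed masks."""
    rng = np.random.default_rng(3000 + trial)
    mask = rng.random((8, 32, 32)) < rng.uniform(0.01, 0.08)
    res = classify_islands(mask, (1.0, 1.0), ConnectivityConfig(min_area_mm2=16.0))
    oracle = _oracle_keep(mask, 1.0, 16.0)
    np.testing.assert_array_equal(res.filtered, oracle)


def test_filtered_mask_is_subset_of_input(rng):
    mask = rng.random((6, 24, 24)) < 0.1
    res = classify_islands(mask, (0.5, 0.5))
    assert not (res.filtered & ~mask).any()


def test_enlarging_an_island_never_demotes_it(rng):
    """Monotonicity: growing any kept island keeps it kept."""
    mask = np.zeros((5, 20, 20), dtype=bool)
    mask[2, 5:9, 5:9] = True  # 16 px = 16 mm^2: definite
    res = classify_islands(mask, (1.0, 1.0))
    assert res.filtered.sum() == 16
    bigger = mask.copy()
    bigger[2, 5:11, 5:11] = True
    res2 = classify_islands(bigger, (1.0, 1.0))
    assert res2.filtered[bigger].all()


def test_face_mode_is_stricter_than_diagonal():
    mask = np.zeros((2, 10, 10), dtype=bool)
    mask[0, 4, 4] = True
    mask[1, 5, 5] = True  # diagonal-only through-plane contact
    diag = classify_islands(mask, (1.0, 1.0), ConnectivityConfig(z_mode="diagonal"))
    face = classify_islands(mask, (1.0, 1.0), ConnectivityConfig(z_mode="face"))
    assert diag.filtered.sum() == 2 and face.filtered.sum() == 0
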