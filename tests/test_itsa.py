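"""Threshold update formula, fixed-point convergence, and the lean safeguard."""

import numpy as np
import pytest

from imfseg.itsa import (
    ItsaConfig,
    MuscleStats,
    fixed_points_bruteforce,
    itsa_update,
    lean_reclassify,
    run_itsa_slice,
    second_round,
)


@pytest.mark.parametrize(
    "sm, sf, expected",
    [
        (100.0, 200.0, 150.0),  # (1 + 100/200) * 100
        (120.0, 120.0, 120.0),  # zero separation collapses to SM
        (50.0, 250.0, 90.0),  # (1 + 200/250) * 50
        (0.0, 10.0, 0.0),
    ],
)
def test_update_formula(sm, sf, expected):
    assert itsa_update(sm, sf) == pytest.approx(expected, abs=1e-12)


def test_update_rejects_zero_fat_signal():
    with pytest.raises(ValueError):
        itsa_update(100.0, 0.0)


def test_update_degenerate_partition_returns_muscle_mean():
    # SF < SM cannot arise from a proper partition; the update collapses
    assert itsa_update(100.0, 50.0) == 100.0


def test_two_level_image_partitions_exactly():
    """A perfect two-level image: every pixel at 200 is fat, at 100 muscle."""
    rng = np.random.default_rng(0)
    img = np.where(rng.random((40, 40)) < 0.2, 200.0, 100.0)
    mask = np.ones_like(img, dtype=bool)
    fat, trace = run_itsa_slice(img, mask, pixel_area_mm2=1.0, config=ItsaConfig(prune_min_area_mm2=0))
    assert trace.converged
    np.testing.assert_array_equal(fat, img == 200.0)
    # the converged threshold is the midpoint Eq-update value
    assert trace.final_threshold == pytest.approx(150.0, abs=0.5)


def _bimodal_values(rng, n=4000):
    mu_m = rng.uniform(60, 120)
    mu_f = mu_m + rng.uniform(80, 150)
    frac = rng.uniform(0.05, 0.3)
    n_f = int(n * frac)
    vals = np.concatenate(
        [
            rng.normal(mu_m, rng.uniform(5, 12), n - n_f),
            rng.normal(mu_f, rng.uniform(8, 18), n_f),
        ]
    )
    return np.clip(np.round(vals), 0, 255)  # 8-bit style histogram


@pytest.mark.parametrize("trial", range(50))
def test_convergence_matches_bruteforce_fixed_point(trial):
    """The iterative solver lands on a fixed point of the update map,
    verified by exhaustive search over all candidate 8-bit thresholds."""
    rng = np.random.default_rng(1000 + trial)
    vals = _bimodal_values(rng)
    img = vals.reshape(-1, 1)
    mask = np.ones_like(img, dtype=bool)
    cfg = ItsaConfig(prune_min_area_mm2=0.0, convergence_tol=0.5)
    fat, trace = run_itsa_slice(img, mask, pixel_area_mm2=1.0, config=cfg)
    assert trace.converged
    fps = fixed_points_bruteforce(vals, tol=cfg.convergence_tol)
    assert fps, "oracle found no fixed point on a bimodal histogram"
    # converged threshold within tolerance of an exhaustively-found fixed point
    assert min(abs(trace.final_threshold - f) for f in fps) <= 2 * cfg.convergence_tol


def test_rerun_from_converged_threshold_is_idempotent():
    rng = np.random.default_rng(5)
    vals = _bimodal_values(rng)
    img = vals.reshape(-1, 1)
    mask = np.ones_like(img, dtype=bool)
    cfg = ItsaConfig(prune_min_area_mm2=0.0)
    fat1, trace1 = run_itsa_slice(img, mask, 1.0, cfg)
    fat2, trace2 = run_itsa_slice(img, mask, 1.0, cfg, seed_threshold=trace1.final_threshold)
    np.testing.assert_array_equal(fat1, fat2)


def test_empty_and_constant_rois_degrade_gracefully():
    img = np.full((8, 8), 100.0)
    none = np.zeros_like(img, dtype=bool)
    fat, trace = run_itsa_slice(img, none, 1.0)
    assert not fat.any() and trace.converged and "empty_roi" in trace.flags
    allm = np.ones_like(img, dtype=bool)
    fat, trace = run_itsa_slice(img, allm, 1.0)
    assert not fat.any() and "constant_roi" in trace.flags


def test_second_round_is_disjoint_and_monotone():
    rng = np.random.default_rng(9)
    img = np.zeros((1, 64, 64))
    img[0] = rng.normal(100, 8, (64, 64))
    img[0, 10:20, 10:40] = 220.0  # bright fat block
    img[0, 25:27, 10:40] = 150.0  # partial-volume band
    mask = np.ones_like(img, dtype=bool)
    cfg = ItsaConfig(prune_min_area_mm2=0)
    from imfseg.itsa import run_itsa

    fat1, _ = run_itsa(img, mask, 1.0, cfg)
    fat2, _ = second_round(img, mask, fat1, 1.0, cfg)
    assert not (fat1 & fat2).any()
    assert (fat1 | fat2).sum() >= fat1.sum()
    # round 2 catches the partial band that round 1 misses
    assert fat2[0, 25:27, 10:40].mean() > 0.5


def test_second_round_empty_when_no_residual_brightness():
    """After round 1 captures every bright voxel of a two-level image, the
    residual is constant and round 2 returns an empty mask."""
    img = np.full((1, 16, 16), 100.0)
    img[0, 4:8, 4:8] = 200.0
    mask = np.ones_like(img, dtype=bool)
    from imfseg.itsa import run_itsa

    fat1, _ = run_itsa(img, mask, 1.0, ItsaConfig(prune_min_area_mm2=0))
    np.testing.assert_array_equal(fat1, img == 200.0)
    fat2, traces = second_round(img, mask, fat1, 1.0, ItsaConfig(prune_min_area_mm2=0))
    assert not fat2.any()
    assert "constant_roi" in traces[0].flags


@pytest.mark.parametrize(
    "offset_sd, kept",
    [(1.9, False), (2.1, True)],
)
def test_lean_reclassification_band(offset_sd, kept):
    """Fat voxels within 2 SD of the round-1 muscle mean return to muscle."""
    stats = MuscleStats(mean=100.0, sd=10.0)
    img = np.array([[100.0 + offset_sd * stats.sd]])
    fat = np.array([[True]])
    cleaned, removed = lean_reclassify(fat, img, stats, sd_multiplier=2.0)
    assert bool(cleaned[0, 0]) is kept
    assert removed == (0 if kept else 1)


def test_lean_phantom_false_fat_fraction_small(lean_case):
    """With zero true fat, the safeguard keeps false fat below 0.5% of the ROI."""
    case = lean_case
    roi_n = case.roi.roi_mask.sum()
    assert case.fat_final.sum() / roi_n < 0.005
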