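"""Fully-automated muscle and bone region-of-interest delineation.

The muscle ROI is the fascia-bounded compartment (muscle plus the
inter-/intra-muscular fat it envelopes) with bone removed and subcutaneous
fat excluded.  Stages per slice:

1. multi-Otsu pre-mask into low / muscle-like / fat-like classes;
2. bone from large low-signal cortical objects plus marrow found by
   z-summation of the fat class (marrow is the only fat structure co-aligned
   axially across all slices);
3. a rough muscle mask (holes filled, small objects dropped, morphological
   closing), flood-filled and traced to a seed contour;
4. convex hull, then coarse-to-fine rounds of a morphological geodesic
   active contour ("snake") to settle on the fascial boundary;
5. removal of subcutaneous-fat overshoot touching the primary bone, with a
   3-D fidelity exception for unsupported single-slice objects.

All size thresholds are stated in physical units (mm^2 / cm^2) and converted
through the pixel spacing so one configuration transfers across resolutions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, measure, morphology, segmentation

from .types import ImageVolume

log = logging.getLogger(__name__)


@dataclass
class SnakeRound:
    """One active-contour refinement round.

    contraction_speed: inward balloon pressure (pixels/iteration scale);
    smoothness: curvature smoothing strength (integer, >=0);
    attraction: edge-attraction gain used to build the inverse-gradient
    potential the contour descends.
    """

    iterations: int
    contraction_speed: float
    smoothness: int
    attraction: float


@dataclass
class RoiConfig:
    cortex_min_area_mm2: float = 234.0
    small_object_max_cm2: float = 60.0
    hole_max_cm2: float = 180.0
    closing_radius_mm: float = 1.5
    snake_rounds: list[SnakeRound] = field(
        default_factory=lambda: [
            SnakeRound(iterations=25, contraction_speed=0.8, smoothness=2, attraction=100.0),
            SnakeRound(iterations=10, contraction_speed=0.3, smoothness=1, attraction=100.0),
            SnakeRound(iterations=4, contraction_speed=0.0, smoothness=1, attraction=100.0),
        ]
    )
    snake_sigma: float = 2.0
    overshoot_enabled: bool = True
    overshoot_min_area_mm2: float = 50.0

    def __post_init__(self) -> None:
        if self.cortex_min_area_mm2 <= 0 or self.small_object_max_cm2 <= 0 or self.hole_max_cm2 <= 0:
            raise ValueError("area thresholds must be positive")
        if len(self.snake_rounds) < 1:
            raise ValueError("at least one snake round is required")


@dataclass
class BoneMask:
    """Per-volume bone segmentation."""

    mask: np.ndarray  # 3-D bool, all bones
    primary: np.ndarray  # 3-D bool, the primary bone (tibia / femur)
    n_bones: int
    found: bool


@dataclass
class RoiDiagnostics:
    """Soft-failure flags accumulated during ROI delineation."""

    snake_reverts: int = 0
    bone_absent: bool = False
    multiple_outer_contours: int = 0


# ---------------------------------------------------------------------------
# pre-mask
# ---------------------------------------------------------------------------

def tissue_premask(slice_image: np.ndarray) -> np.ndarray:
    """Partition a slice into 3 intensity classes {0 low, 1 mid, 2 high}.

    Low captures background/void and cortical bone, mid muscle-like tissue,
    high fat-like tissue (subcutaneous fat, marrow, bright streaks).
    Falls back to a single Otsu split when fewer than 3 distinct values
    are present.
    """
    values = np.unique(slice_image)
    if values.size < 3:
        log.info("fewer than 3 distinct intensities; falling back to single Otsu")
        if values.size < 2:
            return np.zeros(slice_image.shape, dtype=np.uint8)
        t = filters.threshold_otsu(slice_image)
        return np.where(slice_image > t, 2, 0).astype(np.uint8)
    t_low, t_high = filters.threshold_multiotsu(slice_image, classes=3)
    out = np.digitize(slice_image, bins=[t_low, t_high]).astype(np.uint8)
    return out


def premask_volume(volume: ImageVolume) -> np.ndarray:
    """Per-slice 3-class pre-mask for a whole volume."""
    return np.stack([tissue_premask(volume.data[z]) for z in range(volume.slice_count)])


# ---------------------------------------------------------------------------
# bone
# ---------------------------------------------------------------------------

def _area_to_px(area_mm2: float, volume: ImageVolume) -> int:
    return max(1, int(math.ceil(area_mm2 / volume.pixel_area_mm2)))


def segment_bone(
    volume: ImageVolume,
    fat_class: np.ndarray,
    low_class: np.ndarray,
    config: RoiConfig | None = None,
) -> BoneMask:
    """Find bone (cortex + marrow) from the intensity pre-masks.

    Cortices are low-signal objects with area >= ``cortex_min_area_mm2``
    that do not touch the image border (the border-touching low component is
    exterior background).  Marrow is seeded at the maximal cluster of the
    z-summed fat class -- marrow fat is the only bright structure co-aligned
    axially through the stack -- and grown into fat components overlapping
    that seed on each slice.
    """
    config = config or RoiConfig()
    min_px = _area_to_px(config.cortex_min_area_mm2, volume)

    cortex = np.zeros(volume.shape, dtype=bool)
    for z in range(volume.slice_count):
        low = low_class[z].astype(bool)
        low = segmentation.clear_border(low)  # drop exterior background
        labels = measure.label(low, connectivity=2)
        if labels.max() == 0:
            continue
        counts = np.bincount(labels.ravel())
        keep = np.flatnonzero(counts >= min_px)
        keep = keep[keep != 0]
        cortex[z] = np.isin(labels, keep)

    # marrow seed: maximal cluster of the z-summed fat mask.  Subcutaneous
    # fat can also be substantially z-aligned, so among maximal clusters
    # the marrow is identified as the one enclosed by cortex: its border
    # must lie in the retained low-signal (cortical) mask.
    zsum = fat_class.astype(np.int32).sum(axis=0)
    marrow = np.zeros(volume.shape, dtype=bool)
    cortex2d = cortex.any(axis=0)
    if zsum.max() > 0:
        peak = zsum >= max(1, int(0.9 * zsum.max()))
        peak_labels = measure.label(peak, connectivity=2)
        counts = np.bincount(peak_labels.ravel())
        counts[0] = 0
        candidates = np.argsort(counts)[::-1][:10]
        candidates = [int(i) for i in candidates if counts[i] >= 8]
        best, best_score = None, 0.0
        for i in candidates:
            cluster = peak_labels == i
            border = ndi.binary_dilation(cluster, structure=morphology.disk(2)) & ~cluster
            n_border = int(border.sum())
            score = (border & cortex2d).sum() / n_border if n_border else 0.0
            if score > best_score:
                best, best_score = i, score
        if best is None and candidates:
            best = candidates[0]  # no cortex context; fall back to largest
        seed2d = peak_labels == best if best is not None else np.zeros_like(peak)
        for z in range(volume.slice_count):
            fat_labels = measure.label(fat_class[z].astype(bool), connectivity=2)
            hit = np.unique(fat_labels[seed2d & (fat_labels > 0)])
            if hit.size:
                marrow[z] = np.isin(fat_labels, hit)

    bone = cortex | marrow
    # solidify each bone cross-section (annulus + core)
    for z in range(volume.slice_count):
        bone[z] = ndi.binary_fill_holes(bone[z])

    comp, n = ndi.label(bone, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:
        log.warning("no bone found (no low-signal object >= %.0f mm^2)", config.cortex_min_area_mm2)
        return BoneMask(mask=bone, primary=np.zeros_like(bone), n_bones=0, found=False)

    # primary bone = largest mean cross-sectional area
    sizes = ndi.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n + 1))
    primary_label = int(np.argmax(sizes)) + 1
    return BoneMask(mask=bone, primary=comp == primary_label, n_bones=int(n), found=True)


# ---------------------------------------------------------------------------
# muscle seed contour
# ---------------------------------------------------------------------------

def _remove_small_objects(mask: np.ndarray, min_px: int, keep_largest: bool = False) -> np.ndarray:
    """Drop 8-connected objects with area < ``min_px`` (>= is kept).

    With ``keep_largest`` the largest object survives even below the
    threshold, so a fragmented mask degrades instead of vanishing.
    """
    labels, n = ndi.label(mask, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        return mask
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    keep = counts >= min_px
    if keep_largest and not keep.any():
        keep[int(np.argmax(counts))] = True
    return keep[labels]


def _fill_small_holes(mask: np.ndarray, max_px: int) -> np.ndarray:
    """Fill enclosed holes with area < ``max_px``.

    A complement component touching the image border is exterior, not a
    hole, and is never filled regardless of its size.
    """
    inv = ~mask
    labels, n = ndi.label(inv, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        return mask
    border = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    counts = np.bincount(labels.ravel())
    fill = (counts < max_px)
    fill[border[border > 0]] = False
    fill[0] = False
    return mask | fill[labels]


def seed_muscle_mask(
    slice_premask: np.ndarray,
    volume: ImageVolume,
    config: RoiConfig | None = None,
    diagnostics: RoiDiagnostics | None = None,
) -> np.ndarray:
    """Rough muscle-compartment mask for one slice.

    A morphological closing first bridges thin fat streaks that would
    fragment the muscle-like class; objects below ``small_object_max_cm2``
    (partial-volume rings, clutter) are then dropped and enclosed holes
    below ``hole_max_cm2`` (bone void, streaks) filled.  The largest
    remaining object, flood-filled, is the seed; its outline the seed
    muscle contour.
    """
    config = config or RoiConfig()
    mid = slice_premask == 1
    hole_px = _area_to_px(config.hole_max_cm2 * 100.0, volume)
    obj_px = _area_to_px(config.small_object_max_cm2 * 100.0, volume)
    radius_px = max(1, int(round(config.closing_radius_mm / min(volume.spacing_yx))))
    mask = ndi.binary_closing(mid, structure=morphology.disk(radius_px))
    # the closing can also solder stray boundary voxels onto the muscle
    # body through thin necks; a smaller opening cuts those bridges before
    # the convex hull can amplify them
    open_px = max(1, radius_px // 2)
    mask = ndi.binary_opening(mask, structure=morphology.disk(open_px))
    mask = _remove_small_objects(mask, obj_px, keep_largest=True)
    mask = _fill_small_holes(mask, hole_px)
    if not mask.any():
        return mask
    labels = measure.label(mask, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    if (counts > 0).sum() > 1:
        if diagnostics is not None:
            diagnostics.multiple_outer_contours += 1
        log.info("multiple outer contour candidates; keeping largest")
    return labels == int(np.argmax(counts))


def mask_to_contour(mask: np.ndarray) -> np.ndarray:
    """Outer contour of a binary mask as an (N, 2) array of (row, col)."""
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("empty mask has no contour")
    return max(contours, key=lambda c: len(c))


# ---------------------------------------------------------------------------
# fascia refinement (convex hull + snake)
# ---------------------------------------------------------------------------

def refine_fascia(
    seed_mask: np.ndarray,
    slice_image: np.ndarray,
    config: RoiConfig | None = None,
    diagnostics: RoiDiagnostics | None = None,
) -> np.ndarray:
    """Refine a seed muscle mask to the fascial boundary.

    The seed (which follows muscle edges) is first replaced by its convex
    hull -- the fascia is a smooth, nearly elliptical envelope that also
    encloses inter-muscular fat.  Coarse-to-fine rounds of a morphological
    geodesic active contour then settle the hull onto the fascial edge.
    A round that changes the enclosed area by more than 50% is considered
    divergent and reverted.
    """
    config = config or RoiConfig()
    if not seed_mask.any():
        return seed_mask
    hull = morphology.convex_hull_image(seed_mask)

    current = hull
    for rnd in config.snake_rounds:
        gimage = segmentation.inverse_gaussian_gradient(
            slice_image.astype(float), alpha=rnd.attraction, sigma=config.snake_sigma
        )
        refined = segmentation.morphological_geodesic_active_contour(
            gimage,
            num_iter=rnd.iterations,
            init_level_set=current,
            smoothing=rnd.smoothness,
            balloon=-rnd.contraction_speed,
        ).astype(bool)
        prev_area, new_area = current.sum(), refined.sum()
        if new_area == 0 or abs(new_area - prev_area) > 0.5 * prev_area:
            if diagnostics is not None:
                diagnostics.snake_reverts += 1
            log.warning("snake round diverged (area %d -> %d); reverting", prev_area, new_area)
            break
        current = refined
    return ndi.binary_fill_holes(current)


# ---------------------------------------------------------------------------
# overshoot removal
# ---------------------------------------------------------------------------

def remove_overshoot(
    muscle_mask: np.ndarray,
    bone: BoneMask,
    volume: ImageVolume,
    config: RoiConfig | None = None,
) -> np.ndarray:
    """Remove subcutaneous-fat overshoot in contact with the primary bone.

    Within the current muscle mask, fat candidates are found by an Otsu
    threshold; large candidates (>= ``overshoot_min_area_mm2``) that touch
    the primary bone in-plane AND have connected candidate fat on at least
    one neighbouring slice are removed.  Candidates without that 3-D support
    are retained -- a lone bright object on a single slice is more likely
    genuine fat than a systematic fascia error.
    """
    config = config or RoiConfig()
    if not config.overshoot_enabled or not bone.found or not muscle_mask.any():
        return muscle_mask

    min_px = _area_to_px(config.overshoot_min_area_mm2, volume)
    struct8 = np.ones((3, 3), dtype=bool)

    # per-slice candidate fat: Otsu inside the mask, large and bone-touching.
    # The in-mask Otsu split is only meaningful when the histogram really is
    # bimodal; on lean muscle it would split the noise in half and the
    # "bright" half percolates into one huge pseudo-candidate.  A class
    # separation of >= 2 pooled SDs gates the rule.
    candidates = np.zeros(volume.shape, dtype=bool)
    for z in range(volume.slice_count):
        # bone (dark cortex, bright marrow) would distort the in-mask split
        inside = muscle_mask[z] & ~bone.mask[z]
        vals = volume.data[z][inside]
        if vals.size < 16 or np.unique(vals).size < 2:
            continue
        t = filters.threshold_otsu(vals)
        lo, hi = vals[vals <= t], vals[vals > t]
        if lo.size < 2 or hi.size < 2:
            continue
        pooled_sd = math.sqrt((lo.var() + hi.var()) / 2)
        if pooled_sd > 0 and (hi.mean() - lo.mean()) / pooled_sd < 2.0:
            continue  # unimodal slice: nothing fat-like to remove
        fat = inside & (volume.data[z] > t)
        labels = measure.label(fat, connectivity=2)
        if labels.max() == 0:
            continue
        bone_halo = ndi.binary_dilation(bone.primary[z], structure=struct8)
        counts = np.bincount(labels.ravel())
        touching = np.unique(labels[bone_halo & (labels > 0)])
        keep = [i for i in touching if i != 0 and counts[i] >= min_px]
        if keep:
            candidates[z] = np.isin(labels, keep)

    if not candidates.any():
        return muscle_mask

    # 3-D fidelity: only candidates with connected candidate fat on a
    # neighbouring slice are removed
    removed = np.zeros_like(candidates)
    for z in range(volume.slice_count):
        labels = measure.label(candidates[z], connectivity=2)
        for i in range(1, labels.max() + 1):
            comp = labels == i
            support = ndi.binary_dilation(comp, structure=struct8)
            has_z = False
            if z > 0 and (support & candidates[z - 1]).any():
                has_z = True
            if z + 1 < volume.slice_count and (support & candidates[z + 1]).any():
                has_z = True
            if has_z:
                removed[z] |= comp
    return muscle_mask & ~removed


# ---------------------------------------------------------------------------
# final ROI
# ---------------------------------------------------------------------------

def final_roi(
    muscle_mask: np.ndarray, bone: BoneMask, image: ImageVolume
) -> tuple[ImageVolume, np.ndarray]:
    """Subtract bone from the muscle mask and crop the image to the ROI.

    Returns the masked image (intensities outside the ROI zeroed) and the
    final boolean ROI mask.
    """
    roi = muscle_mask & ~bone.mask
    if not roi.any():
        raise ValueError("final ROI is empty")
    return image.with_data(image.data * roi), roi


# ---------------------------------------------------------------------------
# volume driver
# ---------------------------------------------------------------------------

@dataclass
class RoiResult:
    roi_mask: np.ndarray  # final muscle-compartment mask, bone-free
    muscle_mask: np.ndarray  # fascia interior before bone subtraction
    bone: BoneMask
    premask: np.ndarray  # 3-class pre-mask volume
    roi_image: ImageVolume  # intensities masked to the ROI
    diagnostics: RoiDiagnostics


def delineate_roi(
    volume: ImageVolume,
    intensity_source: ImageVolume | None = None,
    config: RoiConfig | None = None,
) -> RoiResult:
    """Run the full automated ROI pipeline on a (preprocessed) volume.

    ``volume`` drives class/contour finding (typically CLAHE-corrected);
    ``intensity_source`` is the image the final binary ROI multiplies
    (typically the raw acquisition) -- defaults to ``volume``.
    """
    config = config or RoiConfig()
    intensity_source = intensity_source or volume
    diagnostics = RoiDiagnostics()

    premask = premask_volume(volume)
    fat_class = premask == 2
    low_class = premask == 0
    bone = segment_bone(volume, fat_class, low_class, config)
    if not bone.found:
        diagnostics.bone_absent = True

    muscle_mask = np.zeros(volume.shape, dtype=bool)
    for z in range(volume.slice_count):
        seed = seed_muscle_mask(premask[z], volume, config, diagnostics)
        if not seed.any():
            continue
        muscle_mask[z] = refine_fascia(seed, volume.data[z], config, diagnostics)

    # overshoot removal is an intensity-statistics step: run it on the same
    # intensities the threshold search sees (the raw image by default)
    muscle_mask = remove_overshoot(muscle_mask, bone, intensity_source, config)
    roi_image, roi_mask = final_roi(muscle_mask, bone, intensity_source)
    return RoiResult(
        roi_mask=roi_mask,
        muscle_mask=muscle_mask,
        bone=bone,
        premask=premask,
        roi_image=roi_image,
        diagnostics=diagnostics,
    )
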