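"""Iterative threshold-seeking algorithm (ITSA).

Muscle/fat separation on T1-weighted images hinges on a threshold that is
unstable across scanners and slices.  ITSA fixes the threshold per slice by
fixed-point iteration: starting from an Otsu seed, partition the ROI,
measure the mean intensity of the segmented muscle (SM_i) and fat (SF_i),
and move the threshold to

    ST_R = (1 + (SF_i - SM_i) / SF_i) * SM_i

until successive thresholds agree.  A second round re-runs the search on the
ROI with round-1 fat removed, picking up partial-volumed fat voxels whose
intensity sits between pure muscle and pure fat.  A post-hoc safeguard
reclassifies "fat" voxels lying within 2 SD of the round-1 muscle mean back
to muscle -- in lean muscle there is no bimodal distribution and the search
would otherwise register noise as fat.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import filters

log = logging.getLogger(__name__)


@dataclass
class ItsaConfig:
    convergence_tol: float = 0.5  # intensity units
    max_iterations: int = 50
    prune_min_area_mm2: float = 4.0  # in-plane island pruning between iterations
    lean_sd_multiplier: float = 2.0
    round2_enabled: bool = True

    def __post_init__(self) -> None:
        if self.convergence_tol < 0:
            raise ValueError("convergence_tol must be >= 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class ThresholdState:
    """One accepted ITSA iteration."""

    ST_R: float
    SM_i: float
    SF_i: float
    iteration: int
    converged: bool


@dataclass
class SliceTrace:
    """Full per-slice iteration record for audit logging."""

    states: list[ThresholdState] = field(default_factory=list)
    converged: bool = False
    flags: list[str] = field(default_factory=list)

    @property
    def final_threshold(self) -> float | None:
        return self.states[-1].ST_R if self.states else None

    def to_dict(self) -> dict:
        return {
            "converged": self.converged,
            "flags": list(self.flags),
            "iterations": [
                {"ST_R": s.ST_R, "SM_i": s.SM_i, "SF_i": s.SF_i, "iteration": s.iteration}
                for s in self.states
            ],
        }


def itsa_update(SM_i: float, SF_i: float) -> float:
    """One threshold update: ST_R = (1 + (SF_i - SM_i)/SF_i) * SM_i.

    Requires SF_i > 0.  A degenerate partition with SF_i < SM_i collapses
    to SM_i (and is flagged by the caller).
    """
    if SF_i <= 0:
        raise ValueError(f"SF_i must be positive, got {SF_i}")
    if SM_i < 0:
        raise ValueError(f"SM_i must be non-negative, got {SM_i}")
    if SF_i < SM_i:
        return SM_i
    return (1.0 + (SF_i - SM_i) / SF_i) * SM_i


def _prune_islands(fat: np.ndarray, min_px: int) -> np.ndarray:
    """Drop in-plane fat islands below ``min_px`` pixels (8-connected)."""
    if min_px <= 1 or not fat.any():
        return fat
    labels, n = ndi.label(fat, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        return fat
    counts = np.bincount(labels.ravel())
    keep = counts >= min_px
    keep[0] = False
    return keep[labels]


def run_itsa_slice(
    roi_values_image: np.ndarray,
    roi_mask: np.ndarray,
    pixel_area_mm2: float,
    config: ItsaConfig | None = None,
    seed_threshold: float | None = None,
) -> tuple[np.ndarray, SliceTrace]:
    """Run ITSA on one slice.

    Parameters
    ----------
    roi_values_image:
        2-D intensity image (values outside ``roi_mask`` ignored).
    roi_mask:
        Boolean mask of ROI pixels on this slice.
    pixel_area_mm2:
        In-plane pixel area, for island pruning in physical units.
    seed_threshold:
        Optional explicit seed; defaults to Otsu on the ROI histogram.

    Returns the converged fat mask (no island pruning applied to the final
    mask -- the 3-D connectivity check handles that downstream) and the full
    iteration trace.
    """
    config = config or ItsaConfig()
    trace = SliceTrace()
    empty = np.zeros_like(roi_mask)
    vals = roi_values_image[roi_mask]
    if vals.size == 0:
        trace.converged = True
        trace.flags.append("empty_roi")
        return empty, trace
    if np.unique(vals).size < 2:
        trace.converged = True
        trace.flags.append("constant_roi")
        return empty, trace

    if seed_threshold is None:
        seed_threshold = float(filters.threshold_otsu(vals))
    min_px = max(1, int(math.ceil(config.prune_min_area_mm2 / pixel_area_mm2)))

    threshold = float(seed_threshold)
    converged = False
    for it in range(1, config.max_iterations + 1):
        fat = roi_mask & (roi_values_image > threshold)
        fat_stat = _prune_islands(fat, min_px)
        if not fat_stat.any():
            trace.converged = True
            trace.flags.append("lean_slice_empty_fat")
            return empty, trace
        muscle = roi_mask & ~fat_stat
        if not muscle.any():
            trace.flags.append("degenerate_all_fat")
            break
        SM = float(roi_values_image[muscle].mean())
        SF = float(roi_values_image[fat_stat].mean())
        if SF < SM:
            trace.flags.append("degenerate_partition")
        new_threshold = itsa_update(SM, SF)
        state = ThresholdState(
            ST_R=new_threshold, SM_i=SM, SF_i=SF, iteration=it, converged=False
        )
        trace.states.append(state)
        if abs(new_threshold - threshold) < config.convergence_tol:
            threshold = new_threshold
            converged = True
            state.converged = True
            break
        threshold = new_threshold

    trace.converged = converged
    if not converged:
        trace.flags.append("non_convergence")
    final_fat = roi_mask & (roi_values_image > threshold)
    return final_fat, trace


def run_itsa(
    roi_image: np.ndarray,
    roi_mask: np.ndarray,
    pixel_area_mm2: float,
    config: ItsaConfig | None = None,
) -> tuple[np.ndarray, list[SliceTrace]]:
    """Run ITSA slice by slice over a 3-D ROI (the threshold is
    slice-specific by design)."""
    config = config or ItsaConfig()
    fat = np.zeros(roi_mask.shape, dtype=bool)
    traces: list[SliceTrace] = []
    for z in range(roi_mask.shape[0]):
        fat[z], trace = run_itsa_slice(roi_image[z], roi_mask[z], pixel_area_mm2, config)
        traces.append(trace)
    return fat, traces


def second_round(
    roi_image: np.ndarray,
    roi_mask: np.ndarray,
    round1_fat: np.ndarray,
    pixel_area_mm2: float,
    config: ItsaConfig | None = None,
) -> tuple[np.ndarray, list[SliceTrace]]:
    """Re-run ITSA on the ROI with round-1 fat subtracted.

    The first pass is not sensitive to partial-volumed fat: those voxels sit
    below the converged threshold.  Removing segmented fat and repeating the
    search lowers the threshold into the partial-volume band.  The returned
    mask is disjoint from round 1 by construction; the final IMF mask is the
    union of both rounds.
    """
    residual_mask = roi_mask & ~round1_fat
    fat2, traces = run_itsa(roi_image, residual_mask, pixel_area_mm2, config)
    return fat2 & ~round1_fat, traces


@dataclass
class MuscleStats:
    """Round-1 muscle intensity statistics used by the lean safeguard."""

    mean: float
    sd: float


def round1_muscle_stats(
    roi_image: np.ndarray, roi_mask: np.ndarray, round1_fat: np.ndarray
) -> MuscleStats:
    """Mean/SD of the muscle partition at round-1 convergence."""
    muscle = roi_mask & ~round1_fat
    vals = roi_image[muscle]
    if vals.size == 0:
        return MuscleStats(mean=float("nan"), sd=float("nan"))
    return MuscleStats(mean=float(vals.mean()), sd=float(vals.std(ddof=0)))


def lean_reclassify(
    fat_mask: np.ndarray,
    roi_image: np.ndarray,
    stats: MuscleStats,
    sd_multiplier: float = 2.0,
) -> tuple[np.ndarray, int]:
    """Reclassify fat voxels within ``sd_multiplier`` SD of the round-1
    muscle mean back to muscle.

    Returns the cleaned fat mask and the number of reclassified voxels.
    """
    if not np.isfinite(stats.mean) or not np.isfinite(stats.sd):
        return fat_mask, 0
    lo = stats.mean - sd_multiplier * stats.sd
    hi = stats.mean + sd_multiplier * stats.sd
    inside_band = fat_mask & (roi_image >= lo) & (roi_image <= hi)
    return fat_mask & ~inside_band, int(inside_band.sum())


# ---------------------------------------------------------------------------
# independent fixed-point oracle (test support)
# ---------------------------------------------------------------------------

def fixed_points_bruteforce(values: np.ndarray, tol: float = 0.5) -> list[float]:
    """Exhaustively locate fixed points of the threshold-update map.

    The induced muscle/fat partition -- and hence the updated threshold --
    is piecewise constant between consecutive distinct intensities, so every
    partition is enumerated by scanning the distinct values.  For the
    partition on [v_k, v_{k+1}) with update u: u is an exact fixed point iff
    it falls inside that interval; otherwise the interval hosts an
    approximate fixed point when u is within ``tol`` of it.  Used as the
    independent oracle for the iterative solver (no island pruning: purely
    histogram-based).
    """
    values = np.asarray(values, dtype=float).ravel()
    distinct = np.unique(values)
    hits: list[float] = []
    for k, t in enumerate(distinct[:-1]):
        upper = distinct[k + 1]
        fat = values > t
        if not fat.any() or fat.all():
            continue
        SM = float(values[~fat].mean())
        SF = float(values[fat].mean())
        if SF <= 0:
            continue
        u = itsa_update(SM, SF)
        if t - tol <= u < upper + tol:
            hits.append(float(u))
    return hits
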