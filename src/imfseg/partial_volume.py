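"""Partial-volume fat-fraction correction.

A voxel thinner than the fat structure it samples mixes muscle and fat
signal.  Assuming signal scales linearly with the fat fraction per voxel,

    SF_max * C + SM_x * (1 - C) = SV_x        (linear mixture)
    C = (SV_x - SM_x) / (SF_max - SM_x)       (isolated fat fraction)

where SF_max is a reference pure-fat intensity (mean of the top quartile of
round-1 IMF voxel intensities; the mean subcutaneous-fat signal is offered
as a sensitivity alternative), SM_x the mean muscle intensity after the
entire IMF segmentation is subtracted, and SV_x the candidate voxel's
intensity.  Voxels at or above SF_max count as full fat; the rest of the
IMF mask receives a per-voxel fraction C in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)


@dataclass
class PartialVolumeConfig:
    sf_mode: str = "top_quartile_imf"  # or "mean_subcutaneous"
    sf_statistic: str = "mean_top_quartile"  # or "p75"
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.sf_mode not in ("top_quartile_imf", "mean_subcutaneous"):
            raise ValueError("sf_mode must be 'top_quartile_imf' or 'mean_subcutaneous'")
        if self.sf_statistic not in ("mean_top_quartile", "p75"):
            raise ValueError("sf_statistic must be 'mean_top_quartile' or 'p75'")


@dataclass
class PartialVolumeModel:
    """Fitted reference intensities for one image volume."""

    SF_max: float
    SM_x: float
    sf_mode: str


def compute_sf_max(
    round1_fat_intensities: np.ndarray,
    mode: str = "top_quartile_imf",
    statistic: str = "mean_top_quartile",
    subcutaneous_intensities: np.ndarray | None = None,
) -> float:
    """Reference pure-fat intensity.

    ``top_quartile_imf``: mean of round-1 IMF intensities at or above their
    75th percentile (round-1 fat passed the full converged threshold, so its
    brightest quartile is virtually pure fat).  ``mean_subcutaneous``: mean
    of subcutaneous-fat voxels.  An empty round-1 mask falls back to the
    subcutaneous mode when possible.
    """
    round1_fat_intensities = np.asarray(round1_fat_intensities, dtype=float).ravel()
    if mode == "top_quartile_imf" and round1_fat_intensities.size == 0:
        if subcutaneous_intensities is not None and np.size(subcutaneous_intensities) > 0:
            log.warning("empty round-1 fat; falling back to mean subcutaneous signal")
            mode = "mean_subcutaneous"
        else:
            raise ValueError("no round-1 fat intensities and no subcutaneous fallback")
    if mode == "mean_subcutaneous":
        if subcutaneous_intensities is None or np.size(subcutaneous_intensities) == 0:
            raise ValueError("mean_subcutaneous mode requires subcutaneous intensities")
        return float(np.mean(subcutaneous_intensities))
    p75 = float(np.percentile(round1_fat_intensities, 75))
    if statistic == "p75":
        return p75
    top = round1_fat_intensities[round1_fat_intensities >= p75]
    return float(top.mean())


def correction_factor(SV_x: float, SM_x: float, SF_max: float) -> float:
    """Fat fraction C = (SV_x - SM_x) / (SF_max - SM_x), clamped to [0, 1].

    Negative raw values (voxel darker than mean muscle, possible under
    noise) clamp to 0 rather than erroring.
    """
    if SF_max <= SM_x:
        raise ValueError(f"degenerate contrast: SF_max ({SF_max}) <= SM_x ({SM_x})")
    c = (SV_x - SM_x) / (SF_max - SM_x)
    return float(min(1.0, max(0.0, c)))


def fit_model(
    roi_image: np.ndarray,
    roi_mask: np.ndarray,
    fat_union: np.ndarray,
    round1_fat: np.ndarray,
    config: PartialVolumeConfig | None = None,
    subcutaneous_intensities: np.ndarray | None = None,
) -> PartialVolumeModel:
    """Estimate SF_max and SM_x for a volume.

    SM_x is the mean over the whole volume of ROI voxels outside the entire
    IMF segmentation (both rounds subtracted).
    """
    config = config or PartialVolumeConfig()
    muscle = roi_mask & ~fat_union
    if not muscle.any():
        raise ValueError("no muscle voxels left after IMF subtraction")
    SM_x = float(roi_image[muscle].mean())
    SF_max = compute_sf_max(
        roi_image[round1_fat],
        mode=config.sf_mode,
        statistic=config.sf_statistic,
        subcutaneous_intensities=subcutaneous_intensities,
    )
    if SF_max <= SM_x:
        raise ValueError(f"degenerate contrast: SF_max ({SF_max}) <= SM_x ({SM_x})")
    return PartialVolumeModel(SF_max=SF_max, SM_x=SM_x, sf_mode=config.sf_mode)


def apply_correction(
    fat_union: np.ndarray,
    roi_image: np.ndarray,
    model: PartialVolumeModel,
) -> np.ndarray:
    """Per-voxel fat fractions over the IMF union mask.

    Voxels with intensity >= SF_max get fraction 1 (full fat, counted in
    NF); voxels below SF_max get C via the linear-mixture inversion
    (partial-volumed, counted in NV).  Returns a float volume, 0 outside
    the mask.
    """
    fractions = np.zeros(roi_image.shape, dtype=np.float64)
    if not fat_union.any():
        return fractions
    vals = roi_image[fat_union]
    denom = model.SF_max - model.SM_x
    if denom <= 0:
        raise ValueError("degenerate contrast in partial-volume model")
    c = (vals - model.SM_x) / denom
    c = np.clip(c, 0.0, 1.0)
    c[vals >= model.SF_max] = 1.0
    fractions[fat_union] = c
    return fractions
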