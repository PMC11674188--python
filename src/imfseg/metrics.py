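"""Final muscle and IMF metric computation.

With NF full-fat voxels, NV partial-volumed voxels carrying fractions C_i,
and NM full muscle voxels inside the ROI:

    IMF_V = (NF + sum C_i) * VoxelVolume
    M_V   = (NM + sum (1 - C_i)) * VoxelVolume
    IMF%  = IMF_V / (IMF_V + M_V) * 100

Every ROI voxel is accounted for exactly once, so IMF_V + M_V equals the
ROI volume (conservation).  Because calf and thigh stacks have different
slice counts, per-slice mean volumes are reported alongside totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class MetricsConfig:
    slice_window: tuple[int, int] | None = None  # (start, stop) slice indices; None = all
    report_cm3: bool = True


#: Protocol presets for slice selection: the 1.0 T calf protocol uses the
#: centre 8 of 10 slices (signal loss at end slices); the 3.0 T thigh
#: protocol uses all 15.
SLICE_PRESETS = {
    "calf_1T": (1, 9),
    "thigh_3T": None,
}


@dataclass
class SegmentationMetrics:
    case_id: str
    NF: int
    NV: int
    NM: int
    C_mean: float
    voxel_volume_mm3: float
    IMF_V_mm3: float
    M_V_mm3: float
    IMF_pct: float
    subcutaneous_V_mm3: float | None = None
    n_slices: int = 0
    per_slice: list[dict] = field(default_factory=list)

    @property
    def IMF_V_cm3(self) -> float:
        return self.IMF_V_mm3 / 1000.0

    @property
    def M_V_cm3(self) -> float:
        return self.M_V_mm3 / 1000.0

    @property
    def IMF_V_per_slice_cm3(self) -> float:
        return self.IMF_V_cm3 / self.n_slices if self.n_slices else float("nan")

    @property
    def M_V_per_slice_cm3(self) -> float:
        return self.M_V_cm3 / self.n_slices if self.n_slices else float("nan")

    def to_dict(self) -> dict:
        d = {
            "case_id": self.case_id,
            "n_slices": self.n_slices,
            "NF": self.NF,
            "NV": self.NV,
            "NM": self.NM,
            "C_mean": self.C_mean,
            "voxel_volume_mm3": self.voxel_volume_mm3,
            "IMF_V_mm3": self.IMF_V_mm3,
            "M_V_mm3": self.M_V_mm3,
            "IMF_V_cm3": self.IMF_V_cm3,
            "M_V_cm3": self.M_V_cm3,
            "IMF_V_per_slice_cm3": self.IMF_V_per_slice_cm3,
            "M_V_per_slice_cm3": self.M_V_per_slice_cm3,
            "IMF_pct": self.IMF_pct,
        }
        if self.subcutaneous_V_mm3 is not None:
            d["subcutaneous_V_cm3"] = self.subcutaneous_V_mm3 / 1000.0
        return d


def compute_metrics(
    fractions: np.ndarray,
    roi_mask: np.ndarray,
    voxel_volume_mm3: float,
    case_id: str = "",
    subcutaneous_mask: np.ndarray | None = None,
    config: MetricsConfig | None = None,
) -> SegmentationMetrics:
    """Aggregate per-voxel fat fractions into volumes and IMF%.

    ``fractions`` holds the fat fraction of every ROI voxel: 1 for full
    fat, (0, 1) for partial-volumed fat, 0 for full muscle.  Voxels outside
    ``roi_mask`` are ignored.  ``slice_window`` restricts the analysed
    slices (half-open, e.g. (1, 9) = centre 8 of 10).
    """
    config = config or MetricsConfig()
    if voxel_volume_mm3 <= 0:
        raise ValueError("voxel volume must be positive")
    roi_mask = roi_mask.astype(bool)
    if config.slice_window is not None:
        z0, z1 = config.slice_window
        sel = np.zeros_like(roi_mask)
        sel[z0:z1] = roi_mask[z0:z1]
        roi_mask = sel
        zs = range(z0, z1)
    else:
        zs = range(roi_mask.shape[0])
    if not roi_mask.any():
        raise ValueError("empty ROI after slice selection")
    fr = np.where(roi_mask, fractions, 0.0)
    if fr.min() < 0 or fr.max() > 1:
        raise ValueError("fractions must lie in [0, 1]")

    full_fat = roi_mask & (fr == 1.0)
    partial = roi_mask & (fr > 0.0) & (fr < 1.0)
    muscle = roi_mask & (fr == 0.0)
    NF = int(full_fat.sum())
    NV = int(partial.sum())
    NM = int(muscle.sum())
    sum_c = float(fr[roi_mask].sum())  # = NF + sum of partial fractions
    IMF_V = sum_c * voxel_volume_mm3
    M_V = (NM + NV - (sum_c - NF)) * voxel_volume_mm3 + 0.0  # NM + sum(1 - C_i)
    C_mean = float(fr[partial].mean()) if NV else 0.0
    IMF_pct = 100.0 * IMF_V / (IMF_V + M_V)

    per_slice = []
    for z in zs:
        m = roi_mask[z]
        if not m.any():
            continue
        sc = float(fr[z][m].sum())
        imf_v = sc * voxel_volume_mm3
        m_v = (int(m.sum()) - sc) * voxel_volume_mm3
        per_slice.append(
            {
                "slice": int(z),
                "IMF_V_mm3": imf_v,
                "M_V_mm3": m_v,
                "IMF_pct": 100.0 * imf_v / (imf_v + m_v) if (imf_v + m_v) > 0 else 0.0,
            }
        )

    sub_v = None
    if subcutaneous_mask is not None:
        sub_v = float(subcutaneous_mask.astype(bool).sum()) * voxel_volume_mm3

    return SegmentationMetrics(
        case_id=case_id,
        NF=NF,
        NV=NV,
        NM=NM,
        C_mean=C_mean,
        voxel_volume_mm3=voxel_volume_mm3,
        IMF_V_mm3=IMF_V,
        M_V_mm3=M_V,
        IMF_pct=IMF_pct,
        subcutaneous_V_mm3=sub_v,
        n_slices=len(per_slice),
        per_slice=per_slice,
    )
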