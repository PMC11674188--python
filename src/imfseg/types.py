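"""Core in-memory containers shared by every pipeline stage.

An :class:`ImageVolume` is a 3-D scalar grid with physical voxel geometry;
a :class:`LabelVolume` is an integer mask aligned to it.  Axis convention
throughout the package: axis 0 is through-plane (z, slices), axes 1-2 are
in-plane (y rows, x columns).  Areas in mm^2 use ``spacing_yx``; volumes in
mm^3 use ``spacing_yx[0] * spacing_yx[1] * slice_thickness``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

#: Canonical label codes for segmentation outputs.
LABEL_CODES: Mapping[str, int] = {
    "background": 0,
    "muscle": 1,
    "fat_round1": 2,
    "fat_round2_partial": 3,
    "bone": 4,
    "subcutaneous_fat": 5,
}

#: Reverse lookup (code -> name).
CODE_NAMES: Mapping[int, str] = {v: k for k, v in LABEL_CODES.items()}


@dataclass
class ImageVolume:
    """A 3-D MR intensity volume with voxel geometry.

    Parameters
    ----------
    data:
        Array of shape ``(slices, rows, cols)``; finite, non-negative
        intensities in arbitrary scanner units.
    spacing_yx:
        In-plane pixel size in mm, ``(row, col)`` order.
    slice_thickness:
        Through-plane voxel extent in mm.
    case_id:
        Free-form identifier carried into reports.
    """

    data: np.ndarray
    spacing_yx: tuple[float, float]
    slice_thickness: float
    case_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3-D data, got shape {self.data.shape}")
        sy, sx = float(self.spacing_yx[0]), float(self.spacing_yx[1])
        if sy <= 0 or sx <= 0:
            raise ValueError(f"in-plane spacing must be positive, got {(sy, sx)}")
        self.spacing_yx = (sy, sx)
        self.slice_thickness = float(self.slice_thickness)
        if self.slice_thickness <= 0:
            raise ValueError("slice thickness must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")
        if self.data.min() < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def slice_count(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    @property
    def pixel_area_mm2(self) -> float:
        """In-plane area of one pixel in mm^2."""
        return self.spacing_yx[0] * self.spacing_yx[1]

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel in mm^3."""
        return self.pixel_area_mm2 * self.slice_thickness

    def with_data(self, data: np.ndarray, case_id: str | None = None) -> "ImageVolume":
        """Copy of this volume with new intensities, geometry unchanged."""
        return replace(
            self, data=np.asarray(data), case_id=self.case_id if case_id is None else case_id
        )


@dataclass
class LabelVolume:
    """Integer label mask aligned voxelwise to a parent :class:`ImageVolume`."""

    labels: np.ndarray
    code_map: Mapping[str, int] = field(default_factory=lambda: dict(LABEL_CODES))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int16)
        if self.labels.ndim != 3:
            raise ValueError(f"expected 3-D labels, got shape {self.labels.shape}")
        allowed = set(self.code_map.values())
        present = set(np.unique(self.labels).tolist())
        unknown = present - allowed
        if unknown:
            raise ValueError(f"unknown label codes present: {sorted(unknown)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)  # type: ignore[return-value]

    def mask(self, name: str) -> np.ndarray:
        """Boolean mask of voxels carrying the named code."""
        return self.labels == self.code_map[name]

    def counts(self) -> dict[str, int]:
        """Voxel count per named class."""
        return {name: int(np.sum(self.labels == code)) for name, code in self.code_map.items()}


def require_aligned(mask: LabelVolume, volume: ImageVolume) -> None:
    """Raise if a label volume is not voxel-aligned to an image volume."""
    if mask.shape != volume.shape:
        raise ValueError(f"label shape {mask.shape} does not match volume shape {volume.shape}")
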