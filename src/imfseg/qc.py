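"""Quality-control flagging and the manual-correction round trip.

Automated fascia delineation fails in a small fraction of cases (fat
merging with subcutaneous fat, motion streaks, noise in lean muscle).  The
workflow here mirrors how such cases are handled in practice: diagnostics
raised during the run set flags; flagged cases are exported as label files,
corrected in an external editor, and re-imported, after which metrics (and
optionally the threshold search) are recomputed inside the corrected ROI.

The open correction dialect is a NIfTI label map with a JSON sidecar.  A
flat-binary ``.tag`` adapter (one byte per voxel, slice-major, dimensions
taken from the parent volume) is provided for editors that exchange raw tag
buffers; the NIfTI dialect is the contract, the adapter best-effort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import volume_io
from .types import LABEL_CODES, ImageVolume, LabelVolume

log = logging.getLogger(__name__)

FLAGS = (
    "imf_merging_with_subQ",
    "motion_streaks",
    "noise_in_lean_muscle",
    "snake_divergence",
    "itsa_nonconvergence",
    "bone_absent",
)


@dataclass
class QcRecord:
    case_id: str
    flags: list[str] = field(default_factory=list)
    status: str = "auto_ok"  # {auto_ok, needs_correction, corrected}

    def add(self, flag: str) -> None:
        if flag not in FLAGS:
            raise ValueError(f"unknown QC flag {flag!r}; known: {FLAGS}")
        if flag not in self.flags:
            self.flags.append(flag)
        if self.status == "auto_ok":
            self.status = "needs_correction"

    def to_dict(self) -> dict:
        return {"case_id": self.case_id, "flags": list(self.flags), "status": self.status}


def flag_case(
    case_id: str,
    *,
    itsa_nonconverged_slices: int = 0,
    snake_reverts: int = 0,
    bone_absent: bool = False,
    lean_reclassified_fraction: float = 0.0,
    lean_fraction_threshold: float = 0.05,
    lean_empty_slices: int = 0,
    n_slices: int = 0,
) -> QcRecord:
    """Build a QC record from pipeline diagnostics.

    The lean-muscle flag fires when the 2-SD safeguard reclassified more
    than ``lean_fraction_threshold`` of the candidate fat, or when at least
    half the slices found no fat distribution at all -- both signatures of
    the missing-bimodality regime where a threshold search registers noise
    as fat.  Visual-review flags (motion streaks, subcutaneous merging) are
    set manually via :meth:`QcRecord.add`.
    """
    record = QcRecord(case_id=case_id)
    if itsa_nonconverged_slices > 0:
        record.add("itsa_nonconvergence")
    if snake_reverts > 0:
        record.add("snake_divergence")
    if bone_absent:
        record.add("bone_absent")
    if lean_reclassified_fraction > lean_fraction_threshold:
        record.add("noise_in_lean_muscle")
    if n_slices > 0 and lean_empty_slices >= max(1, n_slices // 2):
        record.add("noise_in_lean_muscle")
    return record


# ---------------------------------------------------------------------------
# tag export / import
# ---------------------------------------------------------------------------

def export_tags(
    mask: LabelVolume,
    geometry: ImageVolume,
    path: str | Path,
    format: str = "nifti",
) -> Path:
    """Write the current label volume in the correction dialect."""
    path = Path(path)
    if format == "nifti":
        return volume_io.write_labelmap(mask, geometry, path)
    if format == "tag":
        if mask.shape != geometry.shape:
            raise ValueError("mask not aligned to geometry")
        arr = mask.labels.astype(np.uint8)
        path.write_bytes(arr.tobytes(order="C"))
        return path
    raise ValueError(f"unknown tag format {format!r}")


def import_tags(
    path: str | Path,
    geometry: ImageVolume,
    format: str = "nifti",
) -> LabelVolume:
    """Read a corrected label volume and validate geometry and codes.

    Unknown label codes are a hard error listing the offending codes --
    silent acceptance of editor typos would corrupt downstream volumes.
    """
    path = Path(path)
    if format == "nifti":
        mask = volume_io.read_labelmap(path, geometry)
    elif format == "tag":
        raw = np.frombuffer(path.read_bytes(), dtype=np.uint8)
        expected = int(np.prod(geometry.shape))
        if raw.size != expected:
            raise ValueError(
                f"tag file has {raw.size} voxels; volume expects {expected}"
            )
        labels = raw.reshape(geometry.shape).astype(np.int16)
        unknown = sorted(set(np.unique(labels).tolist()) - set(LABEL_CODES.values()))
        if unknown:
            raise ValueError(f"unknown label codes in tag file: {unknown}")
        mask = LabelVolume(labels=labels)
    else:
        raise ValueError(f"unknown tag format {format!r}")
    unknown = sorted(set(np.unique(mask.labels).tolist()) - set(mask.code_map.values()))
    if unknown:
        raise ValueError(f"unknown label codes in corrected file: {unknown}")
    return mask
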