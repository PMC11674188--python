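"""Reading MR volumes and round-tripping label maps.

NIfTI-1 is the native format for both images and label maps (label maps get
a JSON sidecar recording the code map).  DICOM series directories are read
with slices sorted by through-plane position.  Bilateral thigh acquisitions
can be split into left/right sub-volumes at the widest background gap.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom

from .types import LABEL_CODES, ImageVolume, LabelVolume, require_aligned

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# reading image volumes
# ---------------------------------------------------------------------------

def read_volume(path: str | Path, format: str | None = None, case_id: str | None = None) -> ImageVolume:
    """Read an MR volume from a NIfTI file or a DICOM series directory.

    Parameters
    ----------
    path:
        A ``.nii``/``.nii.gz`` file or a directory of DICOM files belonging
        to one series.
    format:
        ``"nifti"`` or ``"dicom_series"``; inferred from ``path`` when None.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "dicom_series" if path.is_dir() else "nifti"
    if format == "nifti":
        return _read_nifti(path, case_id)
    if format == "dicom_series":
        return _read_dicom_series(path, case_id)
    raise ValueError(f"unknown format {format!r}")


def _read_nifti(path: Path, case_id: str | None) -> ImageVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D NIfTI volume, got shape {data.shape}")
    # nibabel stores (x, y, z); we use (z, y, x)
    data = np.transpose(data, (2, 1, 0))
    zooms = img.header.get_zooms()[:3]  # (x, y, z) mm
    spacing_yx = (float(zooms[1]), float(zooms[0]))
    thickness = float(zooms[2])
    if thickness <= 0 or min(spacing_yx) <= 0:
        raise ValueError(f"non-positive voxel geometry in NIfTI header: {zooms}")
    return ImageVolume(
        data=data,
        spacing_yx=spacing_yx,
        slice_thickness=thickness,
        case_id=case_id or path.stem.replace(".nii", ""),
    )


def _read_dicom_series(path: Path, case_id: str | None) -> ImageVolume:
    files = sorted(p for p in path.iterdir() if p.is_file() and not p.name.startswith("."))
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception:  # non-DICOM clutter in the directory
            continue
    if not datasets:
        raise ValueError(f"no readable DICOM files under {path}")

    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(uids) > 1:
        raise ValueError(f"mixed DICOM series in {path}: {sorted(map(str, uids))}")

    first = datasets[0]
    if not hasattr(first, "PixelSpacing"):
        raise ValueError("missing geometry metadata: PixelSpacing (0028,0030)")
    if not hasattr(first, "SliceThickness"):
        raise ValueError("missing geometry metadata: SliceThickness (0018,0050)")

    # order slices by through-plane position, ascending
    def z_of(ds) -> float:
        if hasattr(ds, "ImagePositionPatient"):
            pos = np.asarray(ds.ImagePositionPatient, dtype=float)
            if hasattr(ds, "ImageOrientationPatient"):
                iop = np.asarray(ds.ImageOrientationPatient, dtype=float)
                normal = np.cross(iop[:3], iop[3:])
                return float(np.dot(pos, normal))
            return float(pos[2])
        return float(getattr(ds, "InstanceNumber", 0))

    if hasattr(first, "ImageOrientationPatient"):
        iop = np.asarray(first.ImageOrientationPatient, dtype=float)
        normal = np.cross(iop[:3], iop[3:])
        if abs(normal[2]) < 0.99:
            warnings.warn(
                "non-axial DICOM orientation; treating the series axis as through-plane",
                stacklevel=2,
            )

    datasets.sort(key=z_of)
    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    shapes = {s.shape for s in slices}
    if len(shapes) > 1:
        raise ValueError(f"slices disagree on in-plane shape: {sorted(shapes)}")
    data = np.stack(slices, axis=0)
    data = np.clip(data, 0, None)  # T1 magnitudes; guard negative intercepts
    spacing = [float(v) for v in first.PixelSpacing]  # (row, col)
    return ImageVolume(
        data=data,
        spacing_yx=(spacing[0], spacing[1]),
        slice_thickness=float(first.SliceThickness),
        case_id=case_id or str(getattr(first, "SeriesInstanceUID", path.name)),
    )


# ---------------------------------------------------------------------------
# writing / reading volumes and label maps
# ---------------------------------------------------------------------------

def _affine(volume: ImageVolume) -> np.ndarray:
    sy, sx = volume.spacing_yx
    return np.diag([sx, sy, volume.slice_thickness, 1.0])


def write_volume(volume: ImageVolume, path: str | Path) -> Path:
    """Write an :class:`ImageVolume` as NIfTI-1."""
    path = Path(path)
    data = np.transpose(volume.data, (2, 1, 0))  # back to (x, y, z)
    nib.save(nib.Nifti1Image(data.astype(np.float32), _affine(volume)), str(path))
    return path


def write_labelmap(mask: LabelVolume, geometry: ImageVolume, path: str | Path) -> Path:
    """Write a label map as NIfTI-1 plus a JSON sidecar with the code map."""
    require_aligned(mask, geometry)
    path = Path(path)
    data = np.transpose(mask.labels, (2, 1, 0)).astype(np.int16)
    nib.save(nib.Nifti1Image(data, _affine(geometry)), str(path))
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps({"code_map": dict(mask.code_map)}, indent=2))
    return path


def read_labelmap(path: str | Path, geometry: ImageVolume) -> LabelVolume:
    """Read a label map written by :func:`write_labelmap` and validate alignment."""
    path = Path(path)
    img = nib.load(str(path))
    labels = np.transpose(np.asanyarray(img.dataobj), (2, 1, 0)).astype(np.int16)
    if tuple(labels.shape) != geometry.shape:
        raise ValueError(
            f"label map shape {labels.shape} does not match volume shape {geometry.shape}"
        )
    sidecar = _sidecar_path(path)
    code_map = dict(LABEL_CODES)
    if sidecar.exists():
        code_map = {str(k): int(v) for k, v in json.loads(sidecar.read_text())["code_map"].items()}
    return LabelVolume(labels=labels, code_map=code_map)


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


# ---------------------------------------------------------------------------
# bilateral acquisitions
# ---------------------------------------------------------------------------

def split_bilateral(volume: ImageVolume, background_quantile: float = 0.05) -> tuple[ImageVolume, ImageVolume]:
    """Split a bilateral (two-leg) volume into left/right sub-volumes.

    The cut is placed at the widest contiguous run of background columns
    (columns whose summed intensity is near zero) in the middle half of the
    field of view; each half is then analysed independently.
    """
    profile = volume.data.sum(axis=(0, 1))  # per-column mass
    thresh = background_quantile * profile.max()
    is_bg = profile <= thresh
    n = len(profile)
    lo, hi = n // 4, 3 * n // 4
    best_start, best_len, run_start = None, 0, None
    for i in range(lo, hi):
        if is_bg[i]:
            if run_start is None:
                run_start = i
            if i - run_start + 1 > best_len:
                best_len, best_start = i - run_start + 1, run_start
        else:
            run_start = None
    if best_start is None:
        raise ValueError("no background gap found between legs; volume may be unilateral")
    cut = best_start + best_len // 2
    left = volume.with_data(volume.data[:, :, :cut].copy(), case_id=volume.case_id + "_L")
    right = volume.with_data(volume.data[:, :, cut:].copy(), case_id=volume.case_id + "_R")
    return left, right
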