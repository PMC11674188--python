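"""NIfTI/DICOM reading, label-map round trips, bilateral splitting."""

import numpy as np
import pytest

from imfseg import volume_io
from imfseg.types import LABEL_CODES, ImageVolume, LabelVolume


def _volume(rng, shape=(4, 16, 20), spacing=(0.312, 0.312), thickness=2.0):
    return ImageVolume(
        data=rng.uniform(0, 255, shape),
        spacing_yx=spacing,
        slice_thickness=thickness,
        case_id="t",
    )


def test_nifti_round_trip_preserves_data_and_geometry(rng, tmp_path):
    vol = _volume(rng)
    path = volume_io.write_volume(vol, tmp_path / "v.nii.gz")
    back = volume_io.read_volume(path)
    np.testing.assert_allclose(back.data, vol.data, rtol=1e-6)
    assert back.spacing_yx == pytest.approx(vol.spacing_yx, abs=1e-6)
    assert back.slice_thickness == pytest.approx(vol.slice_thickness, abs=1e-6)


def test_labelmap_round_trip_is_bit_exact(rng, tmp_path):
    vol = _volume(rng)
    labels = rng.integers(0, 6, vol.shape).astype(np.int16)
    mask = LabelVolume(labels=labels)
    path = volume_io.write_labelmap(mask, vol, tmp_path / "m.nii.gz")
    back = volume_io.read_labelmap(path, vol)
    np.testing.assert_array_equal(back.labels, mask.labels)
    assert dict(back.code_map) == dict(LABEL_CODES)
    assert set(np.unique(back.labels)) == set(np.unique(labels))


def test_empty_labelmap_round_trip(rng, tmp_path):
    vol = _volume(rng)
    mask = LabelVolume(labels=np.zeros(vol.shape, dtype=np.int16))
    volume_io.write_labelmap(mask, vol, tmp_path / "m.nii.gz")
    back = volume_io.read_labelmap(tmp_path / "m.nii.gz", vol)
    assert not back.labels.any()


def test_labelmap_shape_mismatch_is_error(rng, tmp_path):
    vol = _volume(rng)
    other = _volume(rng, shape=(4, 8, 8))
    mask = LabelVolume(labels=np.zeros(other.shape, dtype=np.int16))
    with pytest.raises(ValueError):
        volume_io.write_labelmap(mask, vol, tmp_path / "m.nii.gz")


def _write_dicom_series(tmp_path, rng, n_slices=10, shuffled=True):
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    series_uid = generate_uid()
    positions = list(range(n_slices))
    order = rng.permutation(n_slices) if shuffled else np.arange(n_slices)
    arrays = [rng.integers(0, 1000, (16, 16), dtype=np.uint16) for _ in range(n_slices)]
    for file_idx, z in enumerate(order):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.MRImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "MR"
        ds.PixelSpacing = [0.312, 0.312]
        ds.SliceThickness = 2.0
        ds.ImagePositionPatient = [0.0, 0.0, float(positions[z]) * 2.0]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.InstanceNumber = int(file_idx + 1)
        ds.Rows, ds.Columns = 16, 16
        ds.BitsAllocated, ds.BitsStored, ds.HighBit = 16, 16, 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = arrays[z].tobytes()
        ds.save_as(tmp_path / f"img{file_idx:03d}.dcm", enforce_file_format=True)
    return arrays


def test_dicom_series_sorted_by_position(rng, tmp_path):
    """Files written in shuffled order come back sorted by z position."""
    arrays = _write_dicom_series(tmp_path, rng, shuffled=True)
    vol = volume_io.read_volume(tmp_path, format="dicom_series")
    assert vol.slice_count == 10
    assert vol.spacing_yx == (0.312, 0.312) and vol.slice_thickness == 2.0
    for z in range(10):
        np.testing.assert_array_equal(vol.data[z], arrays[z].astype(float))


def test_dicom_missing_geometry_is_hard_error(rng, tmp_path):
    _write_dicom_series(tmp_path, rng, n_slices=2, shuffled=False)
    import pydicom

    for f in tmp_path.glob("*.dcm"):
        ds = pydicom.dcmread(f)
        del ds.PixelSpacing
        ds.save_as(f, enforce_file_format=True)
    with pytest.raises(ValueError, match="PixelSpacing"):
        volume_io.read_volume(tmp_path, format="dicom_series")


def test_single_slice_volume_supported(rng, tmp_path):
    vol = _volume(rng, shape=(1, 16, 16))
    path = volume_io.write_volume(vol, tmp_path / "s.nii.gz")
    back = volume_io.read_volume(path)
    assert back.slice_count == 1


def test_split_bilateral_separates_two_legs(rng):
    leg = np.zeros((3, 40, 40))
    leg[:, 10:30, 5:18] = 100.0  # left leg
    leg[:, 10:30, 24:37] = 120.0  # right leg
    vol = ImageVolume(data=leg, spacing_yx=(1.0, 1.0), slice_thickness=5.0, case_id="bi")
    left, right = volume_io.split_bilateral(vol)
    assert left.data.max() == 100.0 and right.data.max() == 120.0
    assert left.case_id.endswith("_L") and right.case_id.endswith("_R")
    assert left.shape[2] + right.shape[2] == 40


def test_invariants_rejected():
    with pytest.raises(ValueError):
        ImageVolume(data=np.ones((2, 4, 4)), spacing_yx=(0.0, 1.0), slice_thickness=1.0)
    with pytest.raises(ValueError):
        ImageVolume(data=np.full((2, 4, 4), -1.0), spacing_yx=(1.0, 1.0), slice_thickness=1.0)
    with pytest.raises(ValueError):
        LabelVolume(labels=np.full((2, 4, 4), 9, dtype=np.int16))
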