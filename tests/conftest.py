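"""Shared fixtures: tiny phantom cohorts and synthetic DICOM writers."""

import numpy as np
import pytest

from wnetseg.phantoms import generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """20 synthetic patients x 2 slices at 32x32 (fast, patient-structured)."""
    return generate_cohort(20, 2, size=32, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def write_dicom(path, array, instance_number=1, slope=None, intercept=None,
                pixel_spacing=(1.0, 1.0)):
    """Write a minimal secondary-capture DICOM slice for pipeline tests."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.InstanceNumber = instance_number
    ds.Rows, ds.Columns = array.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelSpacing = list(pixel_spacing)
    if slope is not None:
        ds.RescaleSlope = slope
    if intercept is not None:
        ds.RescaleIntercept = intercept
    ds.PixelData = np.ascontiguousarray(array, dtype=np.uint16).tobytes()
    ds.save_as(str(path), enforce_file_format=True)


@pytest.fixture()
def dicom_patient_dir(tmp_path):
    """A 3-slice synthetic patient in the 3Dircadb1 directory layout."""
    rng = np.random.default_rng(0)
    img_dir = tmp_path / "patient_x" / "PATIENT_DICOM"
    mask_dir = tmp_path / "patient_x" / "MASKS_DICOM" / "liver"
    img_dir.mkdir(parents=True)
    mask_dir.mkdir(parents=True)
    masks = []
    for i in range(3):
        img = rng.integers(0, 1200, size=(16, 16)).astype(np.uint16)
        mask = np.zeros((16, 16), dtype=np.uint16)
        if i != 1:  # slice 1 deliberately has no liver
            mask[4:9, 5 + i:11 + i] = 255
        write_dicom(img_dir / f"image_{i}", img, instance_number=i + 1)
        write_dicom(mask_dir / f"image_{i}", mask, instance_number=i + 1)
        masks.append(mask)
    return tmp_path / "patient_x", masks
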