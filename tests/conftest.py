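import numpy as np
import pytest

from stirquant import ImageVolume, PhantomConfig
from stirquant.phantom import default_lesion


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_phantom_config():
    """Default-geometry phantom with one high-contrast lesion."""
    cfg = PhantomConfig()
    return PhantomConfig(lesions=(default_lesion(cfg, contrast=10.0),))


def make_volume(voxels, spacing=(1.0, 1.0, 4.0), gap=0.0, id=""):
    return ImageVolume(np.asarray(voxels, dtype=float), spacing, gap, id=id)


def write_dicom_series(dirpath, volume_u16, pixel_spacing=(1.0, 1.0),
                       thickness=4.0, between=None):
    """Write a minimal single-frame MR DICOM series (one file per slice)."""
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    series_uid = generate_uid()
    for i in range(volume_u16.shape[2]):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = "1.2.840.10008.5.1.4.1.1.4"  # MR
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "MR"
        ds.InstanceNumber = i + 1
        ds.Rows, ds.Columns = volume_u16.shape[:2]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelSpacing = [str(pixel_spacing[0]), str(pixel_spacing[1])]
        ds.SliceThickness = str(thickness)
        if between is not None:
            ds.SpacingBetweenSlices = str(between)
        ds.PixelData = np.ascontiguousarray(
            volume_u16[:, :, i].astype("<u2")).tobytes()
        pydicom.dcmwrite(str(dirpath / f"slice{i:03d}.dcm"), ds,
                         enforce_file_format=True)
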