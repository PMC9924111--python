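"""Minimal DICOM RT Dose export.

Writes a final plan dose grid as a single multi-frame RT Dose object with
the dose-grid scaling tag honored, so the grid can be pulled into viewers
that speak DICOM.  This is an export convenience only: no RT Plan or RT
Structure Set writers, no clinical frame-of-reference management beyond a
self-consistent geometry.
"""

from __future__ import annotations

import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .grids import ImageGrid

RT_DOSE_STORAGE = "1.2.840.10008.5.1.4.1.1.481.2"


def write_rtdose(dose: ImageGrid, path: str) -> None:
    """Write a dose grid (Gy) as an RT Dose file.

    Frames are axial (z) slices; pixel rows run along y and columns along x,
    matching the planner's patient axis convention.
    """
    # (x, y, z) -> frames=z, rows=y, cols=x
    arr = np.ascontiguousarray(np.transpose(dose.values, (2, 1, 0)))
    scaling = max(float(arr.max()), 1e-6) / (2**31 - 1)
    pixels = np.round(arr / scaling).astype(np.uint32)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = RT_DOSE_STORAGE
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(path, {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = RT_DOSE_STORAGE
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.SeriesInstanceUID = generate_uid()
    ds.StudyInstanceUID = generate_uid()
    ds.FrameOfReferenceUID = generate_uid()
    ds.PatientName = "fifplan^phantom"
    ds.PatientID = "FIFPLAN"

    nz, ny, nx = pixels.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows = ny
    ds.Columns = nx
    ds.NumberOfFrames = nz
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.PixelSpacing = [dose.spacing[1], dose.spacing[0]]  # row, column
    ds.ImagePositionPatient = list(dose.origin)
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.GridFrameOffsetVector = [i * dose.spacing[2] for i in range(nz)]
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseGridScaling = scaling
    ds.PixelData = pixels.tobytes()
    ds.save_as(path, enforce_file_format=True)


def read_rtdose(path: str) -> ImageGrid:
    """Read back an RT Dose written by :func:`write_rtdose`."""
    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(np.float64) * float(ds.DoseGridScaling)
    values = np.transpose(arr, (2, 1, 0))
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    dz = float(offsets[1] - offsets[0]) if len(offsets) > 1 else 1.0
    spacing = (float(ds.PixelSpacing[1]), float(ds.PixelSpacing[0]), dz)
    return ImageGrid(values, spacing, tuple(float(x) for x in ds.ImagePositionPatient))
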