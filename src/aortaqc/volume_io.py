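"""CT volume I/O with a fixed canonical axial orientation.

Every stage of the pipeline operates on a :class:`Volume`: a 3D array of
Hounsfield units indexed ``(slice, row, col)`` in a canonical orientation —
slice index increasing toward the feet (inferior), row index increasing
toward the anterior, column index increasing toward the patient's left.
The superior→inferior slice order matters because the slice-of-interest
search spaces ("upper/lower two thirds") and the SOI-2 offset fallback are
direction-dependent; the convention is fixed here, at load time, so the rest
of the code never has to ask.

Volumes whose stored values cannot be mapped to HU (DICOM series without
rescale tags) are rejected rather than guessed: every threshold downstream
(contrast categories, bone exclusion) is HU-absolute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
import SimpleITK as sitk
from pydicom.errors import InvalidDicomError

#: Canonical orientation code (ITK convention: the anatomical direction each
#: voxel axis points toward): columns→Left, rows→Anterior, slices→Inferior.
CANONICAL_ORIENTATION = "LAI"

#: Direction-cosine matrix (row-major, LPS frame) matching the canonical code.
_CANONICAL_DIRECTION = (1.0, 0.0, 0.0, 0.0, -1.0, 0.0, 0.0, 0.0, -1.0)

#: Plausible HU range for CT data (air .. dense metal/bone).
HU_MIN = -1100.0
HU_MAX = 4000.0


class VolumeLoadError(RuntimeError):
    """The input could not be resolved to a single loadable CT volume."""


class VolumeFormatError(ValueError):
    """The input was loadable but violates the format contract."""


@dataclass
class Volume:
    """A 3D CT volume in Hounsfield units, canonically oriented.

    Parameters
    ----------
    voxels
        HU values, shape ``(n_slices, rows, cols)``.
    spacing
        Voxel spacing ``(x, y, z)`` in mm; ``z`` is the inter-slice distance.
    orientation
        Orientation code; always :data:`CANONICAL_ORIENTATION` for volumes
        produced by this module.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    orientation: str = CANONICAL_ORIENTATION
    source: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise VolumeFormatError(
                f"expected a 3D volume, got {self.voxels.ndim} dimensions"
            )
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeFormatError(f"spacing must be three positive floats: {self.spacing}")
        lo, hi = float(self.voxels.min()), float(self.voxels.max())
        if lo < HU_MIN or hi > HU_MAX:
            raise VolumeFormatError(
                f"voxel values [{lo:.1f}, {hi:.1f}] outside plausible HU range "
                f"[{HU_MIN}, {HU_MAX}]; is the volume rescaled to HU?"
            )

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def slice_shape(self) -> tuple[int, int]:
        return self.voxels.shape[1:]  # type: ignore[return-value]

    @property
    def in_plane_spacing(self) -> tuple[float, float]:
        """(x, y) spacing in mm."""
        return self.spacing[0], self.spacing[1]


# ---------------------------------------------------------------------------
# single-file formats (NRRD / NIfTI) via SimpleITK


def load_volume(file_path: str | Path) -> Volume:
    """Load a single-file 3D volume (NRRD or NIfTI-1) already stored in HU.

    The image is reoriented to the canonical axial order regardless of how it
    was stored; spacing is carried over from the file metadata.
    """
    file_path = Path(file_path)
    if not file_path.is_file():
        raise VolumeLoadError(f"no such file: {file_path}")
    try:
        img = sitk.ReadImage(str(file_path))
    except RuntimeError as exc:  # pragma: no cover - sitk message passthrough
        raise VolumeLoadError(f"could not read {file_path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise VolumeFormatError(
            f"{file_path}: expected a 3D volume, got {img.GetDimension()}D"
        )
    img = sitk.DICOMOrient(img, CANONICAL_ORIENTATION)
    voxels = sitk.GetArrayFromImage(img).astype(np.float64)  # (z, y, x)
    spacing = tuple(float(s) for s in img.GetSpacing())  # (x, y, z)
    return Volume(voxels, spacing, source=file_path.as_posix())


def write_nrrd(volume: Volume, file_path: str | Path) -> Path:
    """Write a canonical volume to NRRD (float64, lossless round trip)."""
    file_path = Path(file_path)
    img = sitk.GetImageFromArray(volume.voxels)
    img.SetSpacing(volume.spacing)
    img.SetDirection(_CANONICAL_DIRECTION)
    file_path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(img, str(file_path))
    return file_path


# ---------------------------------------------------------------------------
# DICOM series


def _read_series(directory: Path) -> list[pydicom.Dataset]:
    datasets = []
    for p in sorted(directory.iterdir()):
        if not p.is_file():
            continue
        try:
            ds = pydicom.dcmread(p)
        except (InvalidDicomError, ValueError):
            continue
        if "PixelData" in ds:
            datasets.append(ds)
    if not datasets:
        raise VolumeLoadError(f"no DICOM image files found in {directory}")
    uids = {ds.get("SeriesInstanceUID", "") for ds in datasets}
    if len(uids) != 1:
        raise VolumeLoadError(
            f"{directory} contains {len(uids)} series; expected exactly one"
        )
    return datasets


def load_dicom_series(directory_path: str | Path) -> Volume:
    """Load a single-frame axial CT series as a canonical HU volume.

    Slices are sorted by physical position (most superior first), stored
    values are converted to HU via each file's rescale slope/intercept, and
    the in-plane axes are flipped as needed so that rows increase toward the
    anterior and columns toward the patient's left. Missing rescale or
    spacing tags are an error — silent defaults would corrupt every
    HU-absolute threshold downstream.
    """
    directory = Path(directory_path)
    if not directory.is_dir():
        raise VolumeLoadError(f"no such directory: {directory}")
    datasets = _read_series(directory)

    for tag in ("PixelSpacing", "ImagePositionPatient", "ImageOrientationPatient"):
        if any(tag not in ds for ds in datasets):
            raise VolumeFormatError(f"series in {directory} is missing {tag}")
    if any("RescaleSlope" not in ds or "RescaleIntercept" not in ds for ds in datasets):
        raise VolumeFormatError(
            f"series in {directory} has no rescale tags; stored values cannot "
            "be mapped to HU"
        )

    shapes = {(int(ds.Rows), int(ds.Columns)) for ds in datasets}
    if len(shapes) != 1:
        raise VolumeFormatError(f"inconsistent in-plane shapes in {directory}: {shapes}")

    iop = np.asarray(datasets[0].ImageOrientationPatient, dtype=float)
    col_dir, row_dir = iop[:3], iop[3:]  # along-row / along-column unit vectors
    if abs(col_dir[2]) > 0.01 or abs(row_dir[2]) > 0.01:
        raise VolumeFormatError("non-axial (tilted) series are not supported")
    if abs(abs(col_dir[0]) - 1.0) > 0.01 or abs(abs(row_dir[1]) - 1.0) > 0.01:
        raise VolumeFormatError("in-plane rotated series are not supported")

    # most superior (largest LPS z) first -> slice index increases inferior
    datasets.sort(key=lambda ds: -float(ds.ImagePositionPatient[2]))
    zs = [float(ds.ImagePositionPatient[2]) for ds in datasets]
    if len(zs) < 2:
        raise VolumeFormatError(f"{directory}: need at least two slices")
    dz = np.diff(zs)
    if np.ptp(np.abs(dz)) > 1e-3 or np.any(np.abs(dz) < 1e-6):
        raise VolumeFormatError(f"{directory}: inconsistent inter-slice spacing")
    z_spacing = float(abs(dz[0]))

    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        arr = arr * float(ds.RescaleSlope) + float(ds.RescaleIntercept)
        slices.append(arr)
    voxels = np.stack(slices, axis=0)

    # canonicalize in-plane axes: columns toward Left, rows toward Anterior
    if col_dir[0] < 0:
        voxels = voxels[:, :, ::-1]
    if row_dir[1] > 0:  # rows toward Posterior in the file -> flip
        voxels = voxels[:, ::-1, :]

    ps = datasets[0].PixelSpacing  # (row spacing = y, col spacing = x)
    spacing = (float(ps[1]), float(ps[0]), z_spacing)
    return Volume(np.ascontiguousarray(voxels), spacing, source=directory.as_posix())


_CT_STORAGE_UID = "1.2.840.10008.5.1.4.1.1.2"


def write_dicom_series(volume: Volume, directory: str | Path) -> Path:
    """Write a canonical volume as a minimal single-frame CT DICOM series.

    Stored values are ``round(HU) + 1024`` in uint16 (slope 1, intercept
    -1024), so the round trip through :func:`load_dicom_series` is exact up
    to the 1-HU rescale quantization. Orientation is written so that the
    loader performs no flips.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = pydicom.uid.generate_uid()
    study_uid = pydicom.uid.generate_uid()
    n = volume.n_slices
    sx, sy, sz = volume.spacing
    for i in range(n):
        stored = np.clip(np.round(volume.voxels[i]) + 1024, 0, 4095).astype(np.uint16)
        ds = pydicom.Dataset()
        ds.SOPClassUID = _CT_STORAGE_UID
        ds.SOPInstanceUID = pydicom.uid.generate_uid()
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "CT"
        ds.PatientName = "PHANTOM"
        ds.PatientID = "PHANTOM"
        ds.InstanceNumber = i + 1
        ds.Rows, ds.Columns = stored.shape
        ds.PixelSpacing = [sy, sx]
        ds.SliceThickness = sz
        # columns toward Left, rows toward Anterior (-y in LPS): canonical
        ds.ImageOrientationPatient = [1, 0, 0, 0, -1, 0]
        ds.ImagePositionPatient = [0.0, 0.0, -i * sz]
        ds.RescaleSlope = 1
        ds.RescaleIntercept = -1024
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 12
        ds.HighBit = 11
        ds.PixelRepresentation = 0
        ds.PixelData = stored.tobytes()
        ds.file_meta = pydicom.dataset.FileMetaDataset()
        ds.file_meta.TransferSyntaxUID = pydicom.uid.ExplicitVRLittleEndian
        ds.file_meta.MediaStorageSOPClassUID = ds.SOPClassUID
        ds.file_meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        ds.save_as(directory / f"slice_{i:04d}.dcm", enforce_file_format=True)
    return directory
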