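"""DICOM-series / NIfTI reading and mask writing.

Loading sorts slices by the projection of their position onto the slice
normal (so shuffled files on disk are harmless), checks inter-slice spacing
uniformity, and fills the metadata map with the usual information-panel
fields. Saving writes one derived-image DICOM per input slice, re-using the
input slice's geometry tags with fresh series/instance UIDs, 8-bit {0, 1}
pixel data and — the auto-save contract — the *same filename* as the
corresponding input file, under the output directory. A structured YAML run
summary (weights, iterations, convergence, volumes) can be written
alongside. NIfTI volumes are accepted and emitted as a convenience.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
import yaml

from .errors import GeometryError, SeriesError
from .grid_core import BinaryMask, ImageVolume

logger = logging.getLogger("tumorseg3d")

#: tolerated relative deviation of inter-slice spacing before a warning
SPACING_UNIFORMITY_TOL = 0.01

_INFO_FIELDS = {
    "PatientSex": "PatientSex",
    "PatientAge": "PatientAge",
    "Manufacturer": "Manufacturer",
    "Modality": "Modality",
}


@dataclass
class SeriesIndex:
    """Sorted slice files of one series, with positions along the normal."""

    file_paths: list[Path]
    slice_positions: list[float]  # mm along the slice normal
    uid_info: dict[str, str] = field(default_factory=dict)
    kind: str = "dicom"  # or "nifti"

    def __post_init__(self) -> None:
        self.file_paths = [Path(p) for p in self.file_paths]


def _slice_normal(orientation_rows: np.ndarray) -> np.ndarray:
    return np.cross(orientation_rows[0], orientation_rows[1])


def _load_nifti(path: Path) -> tuple[ImageVolume, SeriesIndex]:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim != 3:
        raise SeriesError(f"expected a 3D NIfTI volume, got ndim={data.ndim}")
    zooms = img.header.get_zooms()[:3]
    affine = img.affine
    orientation = affine[:3, :3] / np.asarray(zooms)
    vol = ImageVolume(
        data,
        tuple(float(z) for z in zooms),
        origin=affine[:3, 3].copy(),
        orientation=orientation.T,
        metadata={"FileFormat": "NIfTI", "Width": str(data.shape[0]), "Height": str(data.shape[1])},
    )
    normal = _slice_normal(vol.orientation)
    positions = [
        float(np.dot(normal, vol.origin + vol.orientation.T @ np.array([0, 0, k * zooms[2]])))
        for k in range(data.shape[2])
    ]
    index = SeriesIndex([path], positions, {"series": str(path)}, kind="nifti")
    return vol, index


def load_series(path) -> tuple[ImageVolume, SeriesIndex]:
    """Read a DICOM series directory (or a single NIfTI / DICOM file).

    Slices are sorted by position along the slice normal; in-plane spacing
    comes from PixelSpacing, inter-slice spacing from the sorted positions
    (warning if non-uniform beyond 1%). Mixed series UIDs and missing
    geometry tags are errors.
    """
    path = Path(path)
    if not path.exists():
        raise SeriesError(f"input path {path} does not exist")
    if path.is_file() and path.suffix in {".nii", ".gz"}:
        return _load_nifti(path)

    files = sorted(p for p in path.iterdir() if p.is_file()) if path.is_dir() else [path]
    datasets = []
    for p in files:
        try:
            datasets.append((p, pydicom.dcmread(str(p))))
        except Exception:
            continue  # non-DICOM clutter (run summaries, truth masks...)
    if not datasets:
        raise SeriesError(f"no readable DICOM files under {path}")

    uids = {str(ds.get("SeriesInstanceUID", "")) for _, ds in datasets}
    if len(uids) > 1:
        raise SeriesError(f"mixed SeriesInstanceUID values in {path}: {sorted(uids)}")

    first = datasets[0][1]
    for tag in ("ImagePositionPatient", "ImageOrientationPatient", "PixelSpacing"):
        if tag not in first:
            raise GeometryError(f"missing geometry tag {tag} in {datasets[0][0].name}")

    iop = np.asarray([float(v) for v in first.ImageOrientationPatient]).reshape(2, 3)
    normal = np.cross(iop[0], iop[1])
    keyed = []
    for p, ds in datasets:
        pos = np.asarray([float(v) for v in ds.ImagePositionPatient])
        keyed.append((float(np.dot(normal, pos)), p, ds))
    keyed.sort(key=lambda t: t[0])
    positions = [t[0] for t in keyed]

    if len(positions) > 1:
        gaps = np.diff(positions)
        if np.any(gaps <= 0):
            raise SeriesError("slice positions are not strictly monotonic")
        dz = float(np.median(gaps))
        if np.max(np.abs(gaps - dz)) / dz > SPACING_UNIFORMITY_TOL:
            logger.warning(
                "non-uniform inter-slice spacing in %s (max deviation %.1f%%)",
                path,
                100 * np.max(np.abs(gaps - dz)) / dz,
            )
    else:
        dz = float(first.get("SliceThickness", 1.0))

    dy, dx = (float(v) for v in first.PixelSpacing)  # PixelSpacing is (row, col)
    slices = []
    for _, _, ds in keyed:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(ds.get("RescaleSlope", 1.0))
        intercept = float(ds.get("RescaleIntercept", 0.0))
        slices.append(arr.T * slope + intercept)  # (rows, cols) -> (x, y)
    data = np.stack(slices, axis=2)

    orientation = np.stack([iop[0], iop[1], normal])
    origin = np.asarray([float(v) for v in keyed[0][2].ImagePositionPatient])
    metadata = {
        "FileFormat": "DICOM",
        "Width": str(data.shape[0]),
        "Height": str(data.shape[1]),
        "PixelSpacing": f"{dx}\\{dy}",
    }
    for key, tag in _INFO_FIELDS.items():
        if tag in first:
            metadata[key] = str(first.get(tag, ""))

    vol = ImageVolume(data, (dx, dy, dz), origin=origin, orientation=orientation,
                      metadata=metadata)
    index = SeriesIndex(
        [t[1] for t in keyed],
        positions,
        {
            "series": str(first.get("SeriesInstanceUID", "")),
            "study": str(first.get("StudyInstanceUID", "")),
        },
    )
    return vol, index


def _mask_dataset(template: pydicom.Dataset, mask_slice: np.ndarray,
                  series_uid: str, instance_number: int) -> pydicom.dataset.FileDataset:
    ds = Dataset()
    for tag in (
        "PatientName", "PatientID", "PatientSex", "PatientAge", "Manufacturer",
        "StudyInstanceUID", "FrameOfReferenceUID", "StudyID", "StudyDate", "StudyTime",
        "ImagePositionPatient", "ImageOrientationPatient", "PixelSpacing",
        "SliceThickness", "SpacingBetweenSlices", "Modality",
    ):
        if tag in template:
            setattr(ds, tag, template.data_element(tag).value)
    ds.SeriesInstanceUID = series_uid
    ds.SOPClassUID = template.SOPClassUID if "SOPClassUID" in template else pydicom.uid.SecondaryCaptureImageStorage
    ds.SOPInstanceUID = generate_uid()
    ds.SeriesDescription = "tumorseg3d segmentation mask"
    ds.ImageType = ["DERIVED", "SECONDARY"]
    ds.InstanceNumber = instance_number
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows, ds.Columns = mask_slice.shape
    ds.BitsAllocated = 8
    ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0
    ds.PixelData = np.ascontiguousarray(mask_slice.astype(np.uint8)).tobytes()

    meta = FileMetaDataset()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    meta.MediaStorageSOPClassUID = ds.SOPClassUID
    meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
    fds = pydicom.dataset.FileDataset(None, ds, file_meta=meta, preamble=b"\0" * 128)
    return fds


def save_mask(
    mask: BinaryMask,
    index: SeriesIndex,
    out_dir,
    summary: dict | None = None,
) -> list[Path]:
    """Write the mask as one DICOM file per input slice (auto-save contract).

    Each output file carries the geometry of the corresponding input slice,
    {0, 1} 8-bit pixels, and the same filename as its input, under
    ``out_dir`` (created if needed). A ``run_summary.yaml`` is written
    alongside when ``summary`` is given.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not os.access(out_dir, os.W_OK):
        raise OSError(f"output directory {out_dir} is not writable")

    written: list[Path] = []
    if index.kind == "nifti":
        if mask.shape[2] != _nifti_nz(index):
            raise GeometryError("mask slice count does not match the NIfTI volume")
        out = out_dir / index.file_paths[0].name
        affine = np.eye(4)
        affine[:3, :3] = mask.orientation.T * np.asarray(mask.spacing)
        affine[:3, 3] = mask.origin
        nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), affine), str(out))
        written.append(out)
    else:
        if mask.shape[2] != len(index.file_paths):
            raise GeometryError(
                f"mask has {mask.shape[2]} slices, series has {len(index.file_paths)}"
            )
        series_uid = generate_uid()
        for k, src in enumerate(index.file_paths):
            template = pydicom.dcmread(str(src))
            if (int(template.Rows), int(template.Columns)) != (mask.shape[1], mask.shape[0]):
                raise GeometryError(f"mask in-plane shape does not match {src.name}")
            mask_slice = mask.data[:, :, k].T  # (x, y) -> (rows, cols)
            fds = _mask_dataset(template, mask_slice, series_uid, k + 1)
            out = out_dir / src.name
            fds.save_as(str(out), enforce_file_format=True)
            written.append(out)

    if summary is not None:
        with open(out_dir / "run_summary.yaml", "w") as fh:
            yaml.safe_dump(summary, fh, sort_keys=False)
    return written


def _nifti_nz(index: SeriesIndex) -> int:
    return len(index.slice_positions)


def write_series(vol: ImageVolume, out_dir, *, modality: str = "MR") -> list[Path]:
    """Fixture writer: emit an ImageVolume as a DICOM series (one file per
    slice, uint16 pixels). Integer-valued volumes round-trip exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if vol.data.min() < 0 or vol.data.max() > 65535:
        raise GeometryError("fixture writer expects intensities in [0, 65535]")

    series_uid = generate_uid()
    study_uid = generate_uid()
    frame_uid = generate_uid()
    dx, dy, dz = vol.spacing
    written: list[Path] = []
    for k in range(vol.shape[2]):
        ds = Dataset()
        ds.PatientName = "PHANTOM^SYNTHETIC"
        ds.PatientID = "PHANTOM"
        ds.PatientSex = vol.metadata.get("PatientSex", "O")
        ds.PatientAge = vol.metadata.get("PatientAge", "000Y")
        ds.Manufacturer = vol.metadata.get("Manufacturer", "tumorseg3d")
        ds.Modality = modality
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.SOPClassUID = pydicom.uid.MRImageStorage
        ds.SOPInstanceUID = generate_uid()
        ds.InstanceNumber = k + 1
        pos = vol.origin + vol.orientation.T @ np.array([0.0, 0.0, k * dz])
        ds.ImagePositionPatient = [float(v) for v in pos]
        ds.ImageOrientationPatient = [float(v) for v in np.concatenate([vol.orientation[0], vol.orientation[1]])]
        ds.PixelSpacing = [dy, dx]  # (row, col)
        ds.SliceThickness = dz
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.Rows, ds.Columns = vol.shape[1], vol.shape[0]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = np.ascontiguousarray(
            np.round(vol.data[:, :, k]).astype(np.uint16).T
        ).tobytes()

        meta = FileMetaDataset()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        meta.MediaStorageSOPClassUID = ds.SOPClassUID
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        fds = pydicom.dataset.FileDataset(None, ds, file_meta=meta, preamble=b"\0" * 128)
        out = out_dir / f"slice_{k:03d}.dcm"
        fds.save_as(str(out), enforce_file_format=True)
        written.append(out)
    return written


def save_mask_nifti(mask: BinaryMask, path) -> Path:
    """Convenience: write a mask as an 8-bit NIfTI label volume."""
    path = Path(path)
    affine = np.eye(4)
    affine[:3, :3] = mask.orientation.T * np.asarray(mask.spacing)
    affine[:3, 3] = mask.origin
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), affine), str(path))
    return path


def load_mask(path) -> BinaryMask:
    """Read a mask series/volume previously written by :func:`save_mask`."""
    vol, _ = load_series(path)
    return BinaryMask(vol.data > 0.5, vol.spacing, vol.origin, vol.orientation,
                      dict(vol.metadata))
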