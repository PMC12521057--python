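"""Read and write axial CT series as single-frame DICOM files.

The loader calibrates stored pixel values to HU with the DICOM rescale
transform (``HU = stored * RescaleSlope + RescaleIntercept``), groups files
by series UID, and sorts slices by their axial position so that slice 0 is
the most inferior.  The writer produces files that round-trip bit-exactly
through the loader, so synthetic phantoms exercise the same code path as
clinical data.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from .volume import CTVolume

__all__ = ["load_ct_series", "load_exam", "write_ct_series"]

logger = logging.getLogger(__name__)

_AXIAL_ORIENTATION = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0)
_REQUIRED = ("PixelSpacing", "RescaleSlope", "RescaleIntercept")


def _is_axial_ct(ds: Dataset) -> bool:
    if getattr(ds, "Modality", None) != "CT":
        return False
    iop = getattr(ds, "ImageOrientationPatient", None)
    if iop is None:
        return True  # tolerate missing orientation; position sort still applies
    return np.allclose([float(v) for v in iop], _AXIAL_ORIENTATION, atol=1e-3)


def load_ct_series(directory_path, series_uid: str | None = None) -> CTVolume:
    """Load one axial CT series from a directory of DICOM files.

    Parameters
    ----------
    directory_path : path-like
        Directory containing >= 2 single-frame CT image files of one series.
    series_uid : str, optional
        Selects one series when the directory mixes several; without it a
        multi-series directory is an error.

    Returns
    -------
    CTVolume
        HU-calibrated, sorted by ascending axial position.

    Raises
    ------
    ValueError
        Missing calibration/geometry attributes, inconsistent in-plane
        dimensions, multiple series without a selector, or a single-slice
        series (adjacent-slice subtraction needs a neighbor).
    """
    directory = Path(directory_path)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for path in files:
        try:
            ds = pydicom.dcmread(path)
        except Exception:  # not a DICOM file; skip silently
            continue
        if not _is_axial_ct(ds):
            logger.warning("skipping non-axial-CT object %s", path.name)
            continue
        datasets.append(ds)
    if not datasets:
        raise ValueError(f"no axial CT DICOM files found in {directory}")

    by_series: dict[str, list[Dataset]] = {}
    for ds in datasets:
        by_series.setdefault(str(getattr(ds, "SeriesInstanceUID", "unknown")), []).append(ds)
    if series_uid is not None:
        if series_uid not in by_series:
            raise ValueError(
                f"series {series_uid!r} not present; found {sorted(by_series)}"
            )
        chosen = by_series[series_uid]
        chosen_uid = series_uid
    elif len(by_series) > 1:
        raise ValueError(
            f"directory {directory} mixes {len(by_series)} series "
            f"({sorted(by_series)}); pass series_uid to select one"
        )
    else:
        (chosen_uid, chosen), = by_series.items()

    if len(chosen) < 2:
        raise ValueError(
            "series has a single slice; the Wisconsin adjacent-slice "
            "subtraction requires at least 2 slices"
        )

    for ds in chosen:
        for attr in _REQUIRED:
            if getattr(ds, attr, None) is None:
                raise ValueError(f"DICOM attribute {attr} missing; cannot calibrate to HU")

    # Sort by axial position; fall back to InstanceNumber if positions absent.
    have_pos = all(getattr(ds, "ImagePositionPatient", None) is not None for ds in chosen)
    if have_pos:
        chosen.sort(key=lambda d: float(d.ImagePositionPatient[2]))
        positions = np.array([float(d.ImagePositionPatient[2]) for d in chosen])
    else:
        logger.warning("ImagePositionPatient missing; ordering slices by InstanceNumber")
        chosen.sort(key=lambda d: int(d.InstanceNumber))
        positions = np.array([float(int(d.InstanceNumber)) for d in chosen])
    if np.any(np.diff(positions) <= 0):
        raise ValueError("duplicate or non-monotone slice positions in series")
    spacings = np.diff(positions)
    if len(spacings) > 1 and not np.allclose(spacings, spacings[0], atol=1e-3):
        warnings.warn(
            "non-uniform slice spacing; adjacent-slice subtraction still uses "
            "index-adjacent slices",
            stacklevel=2,
        )

    shapes = {(int(d.Rows), int(d.Columns)) for d in chosen}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent in-plane dimensions across slices: {shapes}")

    first = chosen[0]
    spacing = (float(first.PixelSpacing[0]), float(first.PixelSpacing[1]))
    hu = np.stack(
        [
            d.pixel_array.astype(np.float64) * float(d.RescaleSlope)
            + float(d.RescaleIntercept)
            for d in chosen
        ]
    )
    return CTVolume(
        slices=hu,
        pixel_spacing_mm=spacing,
        slice_thickness_mm=float(getattr(first, "SliceThickness", 0) or 1.0),
        slice_positions_mm=positions,
        series_id=chosen_uid,
        exam_id=str(getattr(first, "StudyInstanceUID", "unknown")),
    )


def load_exam(exam_dir) -> list[CTVolume]:
    """Load every series of one exam from a directory tree.

    Files may sit flat in ``exam_dir`` or in per-series subdirectories;
    they are grouped by series UID regardless.  Unreadable series are
    skipped with a logged reason; an exam with no loadable series is an
    error.
    """
    exam_dir = Path(exam_dir)
    uids: set[str] = set()
    for path in sorted(exam_dir.rglob("*")):
        if not path.is_file():
            continue
        try:
            ds = pydicom.dcmread(path, stop_before_pixels=True)
        except Exception:
            continue
        uid = getattr(ds, "SeriesInstanceUID", None)
        if uid is not None:
            uids.add(str(uid))
    volumes: list[CTVolume] = []
    for uid in sorted(uids):
        # every series may span subdirectories; search from the exam root
        try:
            volumes.append(_load_series_from_tree(exam_dir, uid))
        except ValueError as exc:
            logger.warning("skipping series %s in %s: %s", uid, exam_dir, exc)
    if not volumes:
        raise ValueError(f"no loadable CT series under {exam_dir}")
    return volumes


def _load_series_from_tree(root: Path, series_uid: str) -> CTVolume:
    """Like :func:`load_ct_series` but searching a directory tree."""
    dirs = {p.parent for p in root.rglob("*") if p.is_file()}
    last_error: Exception | None = None
    for d in sorted(dirs):
        try:
            return load_ct_series(d, series_uid=series_uid)
        except ValueError as exc:
            last_error = exc
    raise ValueError(f"series {series_uid} not loadable under {root}: {last_error}")


def write_ct_series(
    volume: CTVolume,
    directory_path,
    *,
    rescale_slope: float = 1.0,
    rescale_intercept: float = 0.0,
) -> list[Path]:
    """Write a volume as one DICOM file per slice.

    Stored values are signed 16-bit with the given rescale transform; HU
    values must satisfy ``(hu - intercept) / slope ∈ int16`` exactly so that
    ``load_ct_series(write_ct_series(v))`` reproduces the HU array
    bit-exactly.

    Raises
    ------
    ValueError
        If any HU value is not exactly representable in the chosen storage.
    """
    directory = Path(directory_path)
    directory.mkdir(parents=True, exist_ok=True)

    scaled = (volume.slices - rescale_intercept) / rescale_slope
    stored = np.rint(scaled)
    if not np.allclose(scaled, stored, atol=1e-6, rtol=0):
        raise ValueError(
            "HU values are not exactly representable as integers with "
            f"slope={rescale_slope}, intercept={rescale_intercept}"
        )
    if stored.min() < np.iinfo(np.int16).min or stored.max() > np.iinfo(np.int16).max:
        raise ValueError(
            f"stored value range [{stored.min():.0f}, {stored.max():.0f}] "
            "exceeds signed 16-bit storage"
        )
    stored = stored.astype(np.int16)

    # Deterministic UIDs derived from the volume identifiers keep repeated
    # phantom generation byte-reproducible.
    study_uid = generate_uid(entropy_srcs=[volume.exam_id])
    series_uid = generate_uid(entropy_srcs=[volume.exam_id, volume.series_id])
    paths: list[Path] = []
    for i in range(volume.n_slices):
        ds = Dataset()
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = generate_uid(
            entropy_srcs=[volume.exam_id, volume.series_id, str(i)]
        )
        ds.Modality = "CT"
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.PatientName = "PHANTOM"
        ds.PatientID = volume.exam_id
        ds.InstanceNumber = i + 1
        ds.ImageOrientationPatient = list(_AXIAL_ORIENTATION)
        ds.ImagePositionPatient = [0.0, 0.0, float(volume.slice_positions_mm[i])]
        ds.PixelSpacing = [volume.pixel_spacing_mm[0], volume.pixel_spacing_mm[1]]
        ds.SliceThickness = volume.slice_thickness_mm
        ds.Rows, ds.Columns = stored.shape[1], stored.shape[2]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = rescale_slope
        ds.RescaleIntercept = rescale_intercept
        ds.PixelData = stored[i].tobytes()

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = ds.SOPClassUID
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta

        path = directory / f"slice_{i:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths
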