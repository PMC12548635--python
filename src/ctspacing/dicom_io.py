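"""Read and write single-frame DICOM series and reduce them to slice geometry.

A CT series arrives as one file per slice.  The geometry that matters for
slice-spacing QC is one-dimensional: the scalar offset of each slice centre
along the acquisition axis (the normal to the image plane), and the sequence
of gaps between consecutive offsets.  Everything downstream — gap profiling,
sub-volume detection, spacing regularization — operates on that gap sequence.

Slices are ordered by the projection of Image Position (Patient) onto the
geometric normal, not by instance number: viewers reconstruct volumes
geometrically, and the spacing problem this package targets is geometric.
Instance number only breaks exact ties.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.errors import InvalidDicomError
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from .errors import (
    IncompleteGeometryError,
    NonParallelSlicesError,
    SeriesTooSmallError,
)

#: two gaps closer than this (mm) are considered equal throughout the package
GAP_TOLERANCE_MM = 1e-3

#: slice normals deviating by more than this angle (rad) are "non-parallel"
PARALLEL_TOLERANCE_RAD = 1e-3

#: positions are written to DICOM at this many decimal places (DS is 16 bytes)
_POSITION_DECIMALS = 8


@dataclass
class SliceRecord:
    """Spatial metadata (and optionally pixels) of one single-frame slice.

    Positions are slice-centre origins in mm, patient space; voxel indices
    are 0-based.  ``row_dir`` is the direction of increasing column index and
    ``col_dir`` of increasing row index, following the DICOM orientation
    convention.  ``stated_spacing_mm`` is whatever the metadata claims for the
    series (Spacing Between Slices if present, else Slice Thickness) — the
    claim the audit checks, never an input to the geometry itself.
    """

    specimen_id: str
    instance_index: int
    acquisition_index: int
    position_mm: np.ndarray
    row_dir: np.ndarray
    col_dir: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    stated_spacing_mm: Optional[float]
    n_rows: int
    n_cols: int
    pixels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.position_mm = np.asarray(self.position_mm, dtype=float)
        self.row_dir = np.asarray(self.row_dir, dtype=float)
        self.col_dir = np.asarray(self.col_dir, dtype=float)
        for name, v in (("row_dir", self.row_dir), ("col_dir", self.col_dir)):
            if abs(np.linalg.norm(v) - 1.0) > 1e-6:
                raise IncompleteGeometryError(f"{name} is not unit length")
        if abs(float(np.dot(self.row_dir, self.col_dir))) > 1e-6:
            raise IncompleteGeometryError("row_dir and col_dir not orthogonal")
        if min(self.pixel_spacing_mm) <= 0:
            raise IncompleteGeometryError("pixel spacing must be positive")
        if self.stated_spacing_mm is not None and self.stated_spacing_mm <= 0:
            raise IncompleteGeometryError("stated spacing must be positive")

    @property
    def normal(self) -> np.ndarray:
        """Unit normal of the image plane (row_dir x col_dir)."""
        n = np.cross(self.row_dir, self.col_dir)
        return n / np.linalg.norm(n)

    def voxel_to_physical(self, row: float, col: float) -> np.ndarray:
        """Patient-space position of the (possibly fractional) voxel centre."""
        return (
            self.position_mm
            + self.col_dir * self.pixel_spacing_mm[0] * row
            + self.row_dir * self.pixel_spacing_mm[1] * col
        )


@dataclass
class SeriesGeometry:
    """An ordered stack of slices reduced to offsets along the slice normal.

    ``offsets_mm[i]`` is the scalar projection of slice i's position onto
    ``normal``; ``gaps_mm[i] = offsets_mm[i+1] - offsets_mm[i]``.  For a sane
    acquisition the offsets are strictly increasing and every gap positive;
    a violated gap is surfaced by the audit rather than rejected here.
    """

    specimen_id: str
    slices: list[SliceRecord]
    normal: np.ndarray
    offsets_mm: np.ndarray
    gaps_mm: np.ndarray
    stated_spacing_mm: Optional[float] = None

    @classmethod
    def from_slices(
        cls, slices: Sequence[SliceRecord], specimen_id: Optional[str] = None
    ) -> "SeriesGeometry":
        """Sort slices along their common normal and compute the gap sequence.

        Raises
        ------
        SeriesTooSmallError
            If fewer than two slices are supplied.
        NonParallelSlicesError
            If any slice normal deviates from the first by more than
            ``PARALLEL_TOLERANCE_RAD``.
        """
        if len(slices) < 2:
            raise SeriesTooSmallError("series too small: need at least 2 slices")
        normal = slices[0].normal
        for s in slices[1:]:
            cosang = float(np.clip(np.dot(normal, s.normal), -1.0, 1.0))
            if np.arccos(cosang) > PARALLEL_TOLERANCE_RAD:
                raise NonParallelSlicesError(
                    "non-parallel slices: orientation varies within the series"
                )
        projections = [float(np.dot(s.position_mm, normal)) for s in slices]
        order = sorted(
            range(len(slices)), key=lambda i: (projections[i], slices[i].instance_index)
        )
        ordered = [slices[i] for i in order]
        offsets = np.array([projections[i] for i in order], dtype=float)
        stated = ordered[0].stated_spacing_mm
        return cls(
            specimen_id=specimen_id or ordered[0].specimen_id,
            slices=ordered,
            normal=normal,
            offsets_mm=offsets,
            gaps_mm=np.diff(offsets),
            stated_spacing_mm=stated,
        )

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    def extent_mm(self) -> float:
        """Distance between the first and last slice centre."""
        return float(self.offsets_mm[-1] - self.offsets_mm[0])


def _read_slice(path: Path) -> Optional[SliceRecord]:
    try:
        ds = pydicom.dcmread(path)
    except (InvalidDicomError, IsADirectoryError):
        return None
    if "ImagePositionPatient" not in ds or "ImageOrientationPatient" not in ds:
        raise IncompleteGeometryError(
            f"incomplete geometry: {path.name} lacks position/orientation tags"
        )
    iop = [float(v) for v in ds.ImageOrientationPatient]
    stated = None
    if getattr(ds, "SpacingBetweenSlices", None) not in (None, ""):
        stated = float(ds.SpacingBetweenSlices)
    elif getattr(ds, "SliceThickness", None) not in (None, ""):
        stated = float(ds.SliceThickness)
    pixel_spacing = tuple(float(v) for v in getattr(ds, "PixelSpacing", [1.0, 1.0]))
    pixels = None
    if "PixelData" in ds:
        pixels = ds.pixel_array.astype(np.float64)
    return SliceRecord(
        specimen_id=str(getattr(ds, "PatientID", "")) or path.parent.name,
        instance_index=int(getattr(ds, "InstanceNumber", 0)),
        acquisition_index=int(getattr(ds, "AcquisitionNumber", 0) or 0),
        position_mm=np.array([float(v) for v in ds.ImagePositionPatient]),
        row_dir=np.array(iop[:3]),
        col_dir=np.array(iop[3:]),
        pixel_spacing_mm=pixel_spacing,  # DICOM order: (row, column)
        stated_spacing_mm=stated,
        n_rows=int(getattr(ds, "Rows", 0)),
        n_cols=int(getattr(ds, "Columns", 0)),
        pixels=pixels,
    )


def load_series(directory: os.PathLike | str) -> SeriesGeometry:
    """Load every single-frame DICOM file in *directory* into a geometry.

    Files that are not DICOM are skipped.  DICOM files without position or
    orientation tags raise :class:`IncompleteGeometryError`; fewer than two
    usable slices raise :class:`SeriesTooSmallError`.
    """
    directory = Path(directory)
    records = []
    for path in sorted(directory.iterdir()):
        if not path.is_file():
            continue
        rec = _read_slice(path)
        if rec is not None:
            records.append(rec)
    if len(records) < 2:
        raise SeriesTooSmallError(
            f"series too small: {len(records)} usable slice(s) in {directory}"
        )
    return SeriesGeometry.from_slices(records)


def _slice_dataset(rec: SliceRecord, series_uid: str, study_uid: str) -> Dataset:
    ds = Dataset()
    ds.SOPClassUID = CTImageStorage
    ds.SOPInstanceUID = generate_uid()
    ds.SeriesInstanceUID = series_uid
    ds.StudyInstanceUID = study_uid
    ds.Modality = "CT"
    ds.PatientID = rec.specimen_id
    ds.PatientName = rec.specimen_id
    ds.InstanceNumber = rec.instance_index
    ds.AcquisitionNumber = rec.acquisition_index
    ds.ImagePositionPatient = [
        round(float(v), _POSITION_DECIMALS) for v in rec.position_mm
    ]
    ds.ImageOrientationPatient = [
        round(float(v), _POSITION_DECIMALS)
        for v in np.concatenate([rec.row_dir, rec.col_dir])
    ]
    ds.PixelSpacing = [float(rec.pixel_spacing_mm[0]), float(rec.pixel_spacing_mm[1])]
    if rec.stated_spacing_mm is not None:
        ds.SliceThickness = float(rec.stated_spacing_mm)
        ds.SpacingBetweenSlices = float(rec.stated_spacing_mm)
    ds.Rows = rec.n_rows
    ds.Columns = rec.n_cols
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    pixels = rec.pixels
    if pixels is None:
        pixels = np.zeros((rec.n_rows, rec.n_cols))
    ds.PixelData = np.clip(pixels, 0, 65535).astype(np.uint16).tobytes()
    return ds


def write_geometry(geometry: SeriesGeometry, directory: os.PathLike | str) -> list[Path]:
    """Write one DICOM file per slice of *geometry*; returns the file paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    paths = []
    for i, rec in enumerate(geometry.slices):
        ds = _slice_dataset(rec, series_uid, study_uid)
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = ds.SOPClassUID
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta
        path = directory / f"{geometry.specimen_id}_{i + 1:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


def write_series(spec, directory: os.PathLike | str) -> list[Path]:
    """Realize a :class:`~ctspacing.synthetic_data.SyntheticSeriesSpec` on disk.

    Positions follow the spec's sub-volume gap pattern exactly (to the 1e-8 mm
    precision of the DICOM decimal-string encoding); the acquisition-number
    tag increments per sub-volume and the stated-spacing tags carry the
    metadata claim under test.
    """
    from .synthetic_data import make_series  # local import: avoids a cycle

    geometry, _ = make_series(spec)
    return write_geometry(geometry, directory)
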