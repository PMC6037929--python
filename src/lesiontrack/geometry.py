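"""CT volume geometry and the DICOM patient coordinate system.

A CT series is a stack of axial (or tilted) slices.  Each voxel index
``(i, j, k)`` — column, row, slice, 0-based, voxel-center convention —
maps to a physical millimetre position in the DICOM patient frame via

    p = origin + i * col_spacing * row_dir
               + j * row_spacing * col_dir
               + k * slice_spacing * slice_dir

where ``row_dir`` is the direction of increasing column index (the first
orientation triplet in DICOM), ``col_dir`` the direction of increasing
row index (the second triplet), and ``slice_dir`` their cross product.
All cross-timepoint lesion matching happens in this frame.
"""

from __future__ import annotations

import hashlib
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pydicom
from pydicom.errors import InvalidDicomError

__all__ = [
    "ImageGeometry",
    "ImageVolume",
    "GeometryError",
    "load_dicom_series",
    "voxel_to_patient",
    "patient_to_voxel",
]

#: relative tolerance on slice-position gaps before a series is flagged
#: as non-uniformly spaced (mean spacing is then used, with a warning)
SPACING_TOLERANCE = 0.01


class GeometryError(ValueError):
    """Raised for missing, contradictory or degenerate geometry."""


@dataclass(eq=False)
class ImageGeometry:
    """Voxel grid dimensions, spacing and pose in the patient frame.

    Spacings are millimetres.  ``slice_spacing`` is the centre-to-centre
    distance between consecutive slices (derived from slice positions on
    load); ``slice_thickness`` is the reconstructed section thickness and
    is used only as a fallback when a series has a single slice.
    """

    n_cols: int
    n_rows: int
    n_slices: int
    col_spacing: float
    row_spacing: float
    slice_spacing: float
    slice_thickness: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    row_dir: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    col_dir: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    slice_dir: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        for name in ("n_cols", "n_rows", "n_slices"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be strictly positive")
        for name in ("col_spacing", "row_spacing", "slice_spacing", "slice_thickness"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be strictly positive")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        for name in ("row_dir", "col_dir", "slice_dir"):
            v = np.asarray(getattr(self, name), dtype=float).reshape(3)
            if abs(np.linalg.norm(v) - 1.0) > 1e-6:
                raise GeometryError(f"{name} is not unit-norm")
            setattr(self, name, v)
        if abs(float(np.dot(self.row_dir, self.col_dir))) > 1e-6:
            raise GeometryError("row_dir and col_dir are not orthogonal")

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        """Array shape ``(n_slices, n_rows, n_cols)`` of the voxel grid."""
        return (self.n_slices, self.n_rows, self.n_cols)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return self.col_spacing * self.row_spacing * self.slice_spacing

    @property
    def direction_matrix(self) -> np.ndarray:
        """3x3 matrix whose columns are the scaled index axes (mm/index)."""
        return np.column_stack(
            [
                self.col_spacing * self.row_dir,
                self.row_spacing * self.col_dir,
                self.slice_spacing * self.slice_dir,
            ]
        )

    def voxel_to_patient(self, index: Sequence[float] | np.ndarray) -> np.ndarray:
        """Map fractional voxel indices ``(i, j, k)`` to patient mm.

        Accepts a single index triple or an ``(n, 3)`` array.  Fractional
        and out-of-grid indices are permitted (centroids, extrapolation).
        """
        idx = np.asarray(index, dtype=float)
        return self.origin + idx @ self.direction_matrix.T

    def patient_to_voxel(self, point: Sequence[float] | np.ndarray) -> np.ndarray:
        """Exact inverse of :meth:`voxel_to_patient` (fractional output)."""
        a = self.direction_matrix
        if abs(np.linalg.det(a)) < 1e-12:
            raise GeometryError("direction matrix is degenerate (non-invertible)")
        pts = np.asarray(point, dtype=float) - self.origin
        return np.linalg.solve(a, pts.T).T

    def digest(self) -> str:
        """Checksum of spacing/origin/orientation, for mask-geometry binding."""
        parts = np.concatenate(
            [
                [self.n_cols, self.n_rows, self.n_slices],
                [self.col_spacing, self.row_spacing, self.slice_spacing],
                self.origin,
                self.row_dir,
                self.col_dir,
                self.slice_dir,
            ]
        )
        quantized = np.round(np.asarray(parts, dtype=float), 6)
        return hashlib.sha1(quantized.tobytes()).hexdigest()

    def almost_equal(self, other: "ImageGeometry", tol: float = 1e-6) -> bool:
        return self.digest() == other.digest() if tol == 1e-6 else bool(
            self.shape == other.shape
            and np.allclose(self.direction_matrix, other.direction_matrix, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


def voxel_to_patient(g: ImageGeometry, index) -> np.ndarray:
    return g.voxel_to_patient(index)


def patient_to_voxel(g: ImageGeometry, point) -> np.ndarray:
    return g.patient_to_voxel(point)


@dataclass(eq=False)
class ImageVolume:
    """A single CT series: geometry, HU intensities and identifiers."""

    geometry: ImageGeometry
    intensities: np.ndarray
    patient_id: str
    study_uid: str
    series_uid: str
    acquisition_date: str = ""
    modality: str = "CT"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.shape != self.geometry.shape:
            raise GeometryError(
                f"intensity grid shape {self.intensities.shape} does not match "
                f"geometry shape {self.geometry.shape}"
            )
        if not self.study_uid or not self.series_uid:
            raise GeometryError("study_uid and series_uid must be non-empty")


# ----------------------------------------------------------------------
# DICOM reading

_REQUIRED_TAGS = (
    "PixelSpacing",
    "ImageOrientationPatient",
    "ImagePositionPatient",
    "Rows",
    "Columns",
    "StudyInstanceUID",
    "SeriesInstanceUID",
    "PatientID",
)


def _read_datasets(directory: Path) -> list[pydicom.Dataset]:
    datasets = []
    for path in sorted(directory.rglob("*")):
        if not path.is_file():
            continue
        try:
            ds = pydicom.dcmread(path)
        except (InvalidDicomError, OSError, struct.error):
            continue
        datasets.append(ds)
    return datasets


def load_dicom_series(directory: str | Path) -> list[ImageVolume]:
    """Load every CT series found under ``directory``.

    Files are grouped by SeriesInstanceUID; within a series, slices are
    sorted by the projection of ImagePositionPatient onto the slice
    normal.  ``slice_spacing`` is computed from consecutive positions;
    SliceThickness is kept separately (fallback for single-slice series).

    Raises :class:`GeometryError` naming the offending series when
    required geometry tags are missing or contradictory.  Non-uniform
    slice spacing beyond :data:`SPACING_TOLERANCE` triggers a warning
    and the mean spacing is used.
    """
    directory = Path(directory)
    by_series: dict[str, list[pydicom.Dataset]] = {}
    for ds in _read_datasets(directory):
        uid = str(getattr(ds, "SeriesInstanceUID", "")) or "<missing>"
        by_series.setdefault(uid, []).append(ds)
    if not by_series:
        raise GeometryError(f"no DICOM files readable under {directory}")

    volumes = []
    for uid, slices in sorted(by_series.items()):
        volumes.append(_assemble_series(uid, slices))
    return volumes


def _assemble_series(uid: str, slices: list[pydicom.Dataset]) -> ImageVolume:
    for ds in slices:
        missing = [t for t in _REQUIRED_TAGS if getattr(ds, t, None) is None]
        if missing:
            raise GeometryError(f"series {uid}: missing required tags {missing}")

    ref = slices[0]
    orient = np.asarray([float(v) for v in ref.ImageOrientationPatient])
    row_dir, col_dir = orient[:3], orient[3:]
    slice_dir = np.cross(row_dir, col_dir)
    for ds in slices[1:]:
        o = np.asarray([float(v) for v in ds.ImageOrientationPatient])
        if not np.allclose(o, orient, atol=1e-4):
            raise GeometryError(f"series {uid}: contradictory orientation between slices")
        if (ds.Rows, ds.Columns) != (ref.Rows, ref.Columns):
            raise GeometryError(f"series {uid}: inconsistent matrix size")

    positions = np.asarray(
        [[float(v) for v in ds.ImagePositionPatient] for ds in slices]
    )
    order = np.argsort(positions @ slice_dir, kind="stable")
    slices = [slices[i] for i in order]
    positions = positions[order]

    row_spacing, col_spacing = (float(v) for v in ref.PixelSpacing)
    thickness = float(getattr(ref, "SliceThickness", 0) or 0)

    if len(slices) > 1:
        gaps = np.diff(positions @ slice_dir)
        mean_gap = float(np.mean(gaps))
        if mean_gap <= 0:
            raise GeometryError(f"series {uid}: duplicate or non-advancing slice positions")
        if np.ptp(gaps) > SPACING_TOLERANCE * mean_gap:
            warnings.warn(
                f"series {uid}: non-uniform slice spacing "
                f"(gaps {gaps.min():.4f}..{gaps.max():.4f} mm); using mean",
                stacklevel=2,
            )
        slice_spacing = mean_gap
    else:
        slice_spacing = thickness if thickness > 0 else 1.0

    geometry = ImageGeometry(
        n_cols=int(ref.Columns),
        n_rows=int(ref.Rows),
        n_slices=len(slices),
        col_spacing=col_spacing,
        row_spacing=row_spacing,
        slice_spacing=slice_spacing,
        slice_thickness=thickness if thickness > 0 else slice_spacing,
        origin=positions[0],
        row_dir=row_dir,
        col_dir=col_dir,
        slice_dir=slice_dir,
    )

    stack = []
    for ds in slices:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1) or 1)
        intercept = float(getattr(ds, "RescaleIntercept", 0) or 0)
        stack.append(arr * slope + intercept)
    intensities = np.stack(stack)

    return ImageVolume(
        geometry=geometry,
        intensities=intensities,
        patient_id=str(ref.PatientID),
        study_uid=str(ref.StudyInstanceUID),
        series_uid=uid,
        acquisition_date=str(
            getattr(ref, "AcquisitionDate", "") or getattr(ref, "StudyDate", "")
        ),
        modality=str(getattr(ref, "Modality", "CT")),
    )
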