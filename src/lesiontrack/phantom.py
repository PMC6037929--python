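"""Synthetic longitudinal CT phantoms with ellipsoidal lesions.

The generator emulates what the response-assessment workflow consumes: a
patient scanned at several time points, each scan a DICOM CT series
containing lesions whose geometry is known analytically.  Lesions are
axis-aligned ellipsoids rasterized on voxel centres (no partial-volume
anti-aliasing), so diameters and volumes have closed forms and every
downstream measurement can be checked against a truth table.  Per-
timepoint isotropic scale factors shrink or grow each lesion; a global
per-timepoint shift simulates patient repositioning on the couch.

All randomness (noise, jitter) is driven by a recorded seed: the same
spec writes byte-identical studies.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian

from .geometry import ImageGeometry, ImageVolume
from .mask import LesionMask
from .measure import TimepointSummary
from .response import classify

__all__ = [
    "EllipsoidLesion",
    "PhantomTimepoint",
    "PhantomSpec",
    "rasterize_ellipsoid",
    "generate_study",
    "generate_longitudinal_case",
    "write_dicom_series",
    "save_mask_nifti",
    "load_mask_nifti",
    "default_geometry",
    "analytic_truth",
]

_UID_ROOT = "1.2.826.0.1.3680043.10.511"  # test-data UID namespace


def _uid(*parts) -> str:
    digest = hashlib.sha1(".".join(str(p) for p in parts).encode()).hexdigest()
    return f"{_UID_ROOT}.{int(digest[:12], 16)}.{int(digest[12:24], 16)}"


def default_geometry(
    n_cols: int = 64,
    n_rows: int = 64,
    n_slices: int = 20,
    in_plane: float = 0.8,
    slice_spacing: float = 2.5,
    origin=(-25.0, -25.0, 0.0),
) -> ImageGeometry:
    """Axial identity-orientation grid with typical chest/abdomen spacing."""
    return ImageGeometry(
        n_cols=n_cols, n_rows=n_rows, n_slices=n_slices,
        col_spacing=in_plane, row_spacing=in_plane,
        slice_spacing=slice_spacing, slice_thickness=slice_spacing,
        origin=np.asarray(origin, dtype=float),
    )


@dataclass
class EllipsoidLesion:
    """Axis-aligned ellipsoid in patient mm: centre and semi-axes (a, b, c)."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    hu: float = -20.0  # lesion attenuation
    label: str = "L1"
    organ: str = "other"

    def volume(self, scale: float = 1.0) -> float:
        a, b, c = (s * scale for s in self.semi_axes)
        return 4.0 / 3.0 * np.pi * a * b * c

    def inplane_diameter(self, scale: float = 1.0) -> float:
        # axial orientation: (a, b) are the in-plane semi-axes
        return 2.0 * scale * max(self.semi_axes[0], self.semi_axes[1])

    def inplane_width(self, scale: float = 1.0) -> float:
        return 2.0 * scale * min(self.semi_axes[0], self.semi_axes[1])


@dataclass
class PhantomTimepoint:
    date: str  # YYYYMMDD
    scales: list[float]  # one isotropic factor per lesion (0 allowed: vanished)
    shift: tuple[float, float, float] = (0.0, 0.0, 0.0)  # couch repositioning, mm


@dataclass
class PhantomSpec:
    geometry: ImageGeometry
    lesions: list[EllipsoidLesion]
    timepoints: list[PhantomTimepoint]
    background_hu: float = -70.0
    noise_sd: float = 10.0
    seed: int = 0
    patient_id: str = "PHANTOM-001"

    def __post_init__(self) -> None:
        for tp in self.timepoints:
            if len(tp.scales) != len(self.lesions):
                raise ValueError("each timepoint needs one scale factor per lesion")
            if any(s < 0 for s in tp.scales):
                raise ValueError("scale factors must be >= 0")
        self._check_fit()

    def _check_fit(self) -> None:
        g = self.geometry
        hi = np.array([g.n_cols, g.n_rows, g.n_slices]) - 0.5
        for tp in self.timepoints:
            for lesion, s in zip(self.lesions, tp.scales):
                if s == 0:
                    continue
                c = np.asarray(lesion.center) + np.asarray(tp.shift)
                r = s * np.asarray(lesion.semi_axes)
                for corner in (c - r, c + r):
                    ijk = g.patient_to_voxel(corner)
                    if np.any(ijk < -0.5) or np.any(ijk > hi):
                        raise ValueError(
                            f"lesion {lesion.label} (scale {s}) does not fit inside "
                            f"the grid at timepoint {tp.date}"
                        )


def rasterize_ellipsoid(
    center, semi_axes, g: ImageGeometry, **identity
) -> LesionMask:
    """Voxel is set iff its centre satisfies the ellipsoid inequality.

    ``center`` and ``semi_axes`` are patient-frame mm; semi-axes are
    aligned with the patient axes.  A fully outside ellipsoid yields an
    empty mask with a warning.
    """
    semi = np.asarray(semi_axes, dtype=float)
    if np.any(semi <= 0):
        raise ValueError("semi-axes must be strictly positive")
    kk, rr, cc = np.meshgrid(
        np.arange(g.n_slices), np.arange(g.n_rows), np.arange(g.n_cols),
        indexing="ij",
    )
    idx = np.stack([cc, rr, kk], axis=-1).reshape(-1, 3)
    pts = g.voxel_to_patient(idx)
    q = ((pts - np.asarray(center, dtype=float)) / semi) ** 2
    inside = (q.sum(axis=1) <= 1.0).reshape(g.shape)
    if not inside.any():
        warnings.warn("ellipsoid lies fully outside the voxel grid", stacklevel=2)
    return LesionMask(geometry=g, voxels=inside.astype(np.uint8), **identity)


def generate_study(
    spec: PhantomSpec, timepoint_index: int
) -> tuple[ImageVolume, list[LesionMask]]:
    """Render one time point: HU volume plus noise-free truth masks.

    Intensities are background + lesion HU inside each (scaled, shifted)
    lesion + seeded Gaussian noise.  Overlapping lesions are rejected so
    the per-lesion ground truth stays unambiguous.  Study and series
    UIDs are fresh per timepoint but deterministic in (seed, timepoint).
    """
    tp = spec.timepoints[timepoint_index]
    g = spec.geometry
    masks: list[LesionMask] = []
    occupancy = np.zeros(g.shape, dtype=np.int32)
    intensities = np.full(g.shape, spec.background_hu, dtype=np.float64)
    for lesion, s in zip(spec.lesions, tp.scales):
        if s == 0:
            mask = LesionMask(
                geometry=g, voxels=np.zeros(g.shape, dtype=np.uint8),
                lesion_id=lesion.label, organ_label=lesion.organ,
            )
        else:
            center = np.asarray(lesion.center) + np.asarray(tp.shift)
            mask = rasterize_ellipsoid(
                center, s * np.asarray(lesion.semi_axes), g,
                lesion_id=lesion.label, organ_label=lesion.organ,
            )
        occupancy += mask.voxels
        intensities[mask.voxels.astype(bool)] = lesion.hu
        masks.append(mask)
    if occupancy.max(initial=0) > 1:
        raise ValueError(f"lesions overlap at timepoint {tp.date}; ground truth ambiguous")

    rng = np.random.default_rng((spec.seed, timepoint_index))
    if spec.noise_sd > 0:
        intensities = intensities + rng.normal(0.0, spec.noise_sd, size=g.shape)
    intensities = np.clip(np.round(intensities), -1024, 3071).astype(np.int16)

    study_uid = _uid(spec.patient_id, spec.seed, timepoint_index, "study")
    series_uid = _uid(spec.patient_id, spec.seed, timepoint_index, "series")
    volume = ImageVolume(
        geometry=g,
        intensities=intensities,
        patient_id=spec.patient_id,
        study_uid=study_uid,
        series_uid=series_uid,
        acquisition_date=tp.date,
    )
    for m in masks:
        m.series_uid = series_uid
    return volume, masks


def write_dicom_series(volume: ImageVolume, directory: str | Path) -> list[Path]:
    """Write one slice-per-file CT series (explicit VR little endian)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    g = volume.geometry
    data = np.asarray(volume.intensities)
    if data.dtype != np.int16:
        data = np.round(data).astype(np.int16)
    paths = []
    for k in range(g.n_slices):
        sop_uid = _uid(volume.series_uid, "slice", k)
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = sop_uid
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = pydicom.Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = sop_uid
        ds.Modality = "CT"
        ds.PatientID = volume.patient_id
        ds.PatientName = volume.patient_id
        ds.StudyInstanceUID = volume.study_uid
        ds.SeriesInstanceUID = volume.series_uid
        ds.StudyDate = volume.acquisition_date
        ds.SeriesDate = volume.acquisition_date
        ds.AcquisitionDate = volume.acquisition_date
        ds.SeriesNumber = 1
        ds.InstanceNumber = k + 1
        ds.ImageOrientationPatient = [*map(float, g.row_dir), *map(float, g.col_dir)]
        ds.ImagePositionPatient = [float(x) for x in g.voxel_to_patient((0, 0, k))]
        ds.PixelSpacing = [g.row_spacing, g.col_spacing]
        ds.SliceThickness = g.slice_thickness
        ds.Rows = g.n_rows
        ds.Columns = g.n_cols
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed (HU can be negative)
        ds.RescaleIntercept = "0"
        ds.RescaleSlope = "1"
        ds.PixelData = np.ascontiguousarray(data[k]).tobytes()

        path = directory / f"slice{k:03d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


# ----------------------------------------------------------------------
# NIfTI mask exchange (voxel grids 0/1, affine = voxel->patient map)


def save_mask_nifti(mask: LesionMask, path: str | Path) -> None:
    import nibabel as nib

    g = mask.geometry
    affine = np.eye(4)
    affine[:3, :3] = g.direction_matrix
    affine[:3, 3] = g.origin
    # nibabel's first array axis is the fastest-varying voxel index, so
    # store as (col, row, slice)
    data = mask.voxels.transpose(2, 1, 0).astype(np.uint8)
    nib.save(nib.Nifti1Image(data, affine), str(path))


def load_mask_nifti(path: str | Path, g: ImageGeometry, **identity) -> LesionMask:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.shape != (g.n_cols, g.n_rows, g.n_slices):
        raise ValueError(
            f"mask grid {data.shape} does not match series grid "
            f"{(g.n_cols, g.n_rows, g.n_slices)}"
        )
    voxels = (data > 0).astype(np.uint8).transpose(2, 1, 0)
    return LesionMask(geometry=g, voxels=voxels, **identity)


# ----------------------------------------------------------------------
# analytic truth


def analytic_truth(spec: PhantomSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Closed-form lesion measurements and expected response categories.

    Returns ``(lesions, response)`` frames: per-lesion analytic diameter,
    perpendicular width and volume at every timepoint, and the response
    category each criterion must assign to every follow-up given those
    analytic burdens.
    """
    lesion_rows = []
    summaries = []
    for t, tp in enumerate(spec.timepoints):
        sld = spd = vol = 0.0
        for lesion, s in zip(spec.lesions, tp.scales):
            d = lesion.inplane_diameter(s)
            w = lesion.inplane_width(s)
            v = lesion.volume(s) if s > 0 else 0.0
            lesion_rows.append(
                {
                    "timepoint_index": t, "date": tp.date, "lesion": lesion.label,
                    "scale": s, "diameter_mm": d, "width_mm": w,
                    "product_mm2": d * w, "volume_mm3": v,
                }
            )
            sld += d
            spd += d * w
            vol += v
        summaries.append(
            TimepointSummary(timepoint=tp.date, SLD=sld, SPD=spd,
                             total_volume=vol, n_lesions=len(spec.lesions))
        )

    response_rows = []
    baseline, rest = summaries[0], summaries[1:]
    for t, current in enumerate(rest, start=1):
        for crit in ("RECIST", "WHO", "VOLUME"):
            label = classify(crit, baseline, rest[: t - 1], current)
            response_rows.append(
                {
                    "timepoint_index": t, "date": current.timepoint,
                    "criterion": crit, "category": label.category,
                    "pct_from_baseline": label.pct_change_from_baseline,
                    "pct_from_nadir": label.pct_change_from_nadir,
                }
            )
    return pd.DataFrame(lesion_rows), pd.DataFrame(response_rows)


def generate_longitudinal_case(spec: PhantomSpec, out_dir: str | Path) -> dict:
    """Write a complete on-disk case: DICOM per timepoint, truth masks
    (NIfTI) and analytic truth tables (CSV), plus a case manifest."""
    if len(spec.timepoints) < 2:
        raise ValueError("a longitudinal case needs at least 2 timepoints")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest = {"patient_id": spec.patient_id, "seed": spec.seed, "timepoints": []}
    for t, tp in enumerate(spec.timepoints):
        volume, masks = generate_study(spec, t)
        tp_dir = out_dir / f"tp{t:02d}"
        write_dicom_series(volume, tp_dir / "dicom")
        mask_dir = tp_dir / "masks"
        mask_dir.mkdir(parents=True, exist_ok=True)
        mask_files = {}
        for m in masks:
            p = mask_dir / f"{m.lesion_id}.nii"
            save_mask_nifti(m, p)
            mask_files[m.lesion_id] = str(p.relative_to(out_dir))
        manifest["timepoints"].append(
            {
                "index": t, "date": tp.date,
                "study_uid": volume.study_uid, "series_uid": volume.series_uid,
                "dicom_dir": str((tp_dir / "dicom").relative_to(out_dir)),
                "masks": mask_files,
                "organ_labels": {l.label: l.organ for l in spec.lesions},
            }
        )

    truth_lesions, truth_response = analytic_truth(spec)
    truth_lesions.to_csv(out_dir / "truth_lesions.csv", index=False)
    truth_response.to_csv(out_dir / "truth_response.csv", index=False)
    (out_dir / "case.json").write_text(json.dumps(manifest, indent=2))
    return manifest
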