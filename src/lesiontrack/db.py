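"""Relational lesion store: patient, study, series, user, lesion.

A single-file SQLite database mirrors the five-table schema used by the
assessment platform: the DICOM hierarchy (patient -> study -> series,
linked by their globally unique identifiers), a user table so multiple
readers can delineate the same lesion and keep their contours as
separate rows, and a lesion table holding the DEFLATE-compressed mask
payload together with its denormalized measurements.

The uniqueness rule on lesions is (series_uid, user_id, lesion_label):
re-saving the same triplet replaces the row (last write wins) and bumps
the modified timestamp; distinct readers never collide.
"""

from __future__ import annotations

import datetime as _dt
import json
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import ImageGeometry, ImageVolume
from .mask import CompressedMask, LesionMask, MaskError, compress_mask, decompress_mask
from .measure import MeasurementRecord

__all__ = ["LesionStore", "StoreError", "IntegrityReport"]


class StoreError(ValueError):
    """Raised for foreign-key violations and identifier collisions."""


_SCHEMA = """
CREATE TABLE IF NOT EXISTS patient (
    patient_id TEXT PRIMARY KEY,
    name TEXT DEFAULT ''
);
CREATE TABLE IF NOT EXISTS study (
    study_uid TEXT PRIMARY KEY,
    patient_id TEXT NOT NULL REFERENCES patient(patient_id),
    study_date TEXT DEFAULT ''
);
CREATE TABLE IF NOT EXISTS series (
    series_uid TEXT PRIMARY KEY,
    study_uid TEXT NOT NULL REFERENCES study(study_uid),
    modality TEXT DEFAULT 'CT',
    geometry_json TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS user (
    user_id TEXT PRIMARY KEY,
    display_name TEXT DEFAULT ''
);
CREATE TABLE IF NOT EXISTS lesion (
    lesion_id INTEGER PRIMARY KEY AUTOINCREMENT,
    series_uid TEXT NOT NULL REFERENCES series(series_uid),
    user_id TEXT NOT NULL REFERENCES user(user_id),
    lesion_label TEXT NOT NULL,
    organ_label TEXT NOT NULL DEFAULT 'other',
    payload BLOB NOT NULL,
    n_cols INTEGER NOT NULL,
    n_rows INTEGER NOT NULL,
    n_slices INTEGER NOT NULL,
    geometry_digest TEXT NOT NULL,
    timepoint TEXT DEFAULT '',
    unidimensional_mm REAL DEFAULT 0,
    bidimensional_mm2 REAL DEFAULT 0,
    volume_mm3 REAL DEFAULT 0,
    diameter_slice INTEGER DEFAULT -1,
    perpendicular_width_mm REAL DEFAULT 0,
    created TEXT NOT NULL,
    modified TEXT NOT NULL,
    UNIQUE (series_uid, user_id, lesion_label)
);
"""


def _geometry_to_json(g: ImageGeometry) -> str:
    return json.dumps(
        {
            "n_cols": g.n_cols, "n_rows": g.n_rows, "n_slices": g.n_slices,
            "col_spacing": g.col_spacing, "row_spacing": g.row_spacing,
            "slice_spacing": g.slice_spacing, "slice_thickness": g.slice_thickness,
            "origin": g.origin.tolist(), "row_dir": g.row_dir.tolist(),
            "col_dir": g.col_dir.tolist(), "slice_dir": g.slice_dir.tolist(),
        }
    )


def _geometry_from_json(s: str) -> ImageGeometry:
    d = json.loads(s)
    return ImageGeometry(**{k: (np.asarray(v) if isinstance(v, list) else v) for k, v in d.items()})


@dataclass
class IntegrityReport:
    findings: list[str] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not self.findings

    def __str__(self) -> str:
        if self.clean:
            return "integrity: clean"
        return "integrity: " + "; ".join(self.findings)


class LesionStore:
    """Open (creating if needed) the single-file lesion database."""

    def __init__(self, path: str | Path = ":memory:"):
        self.path = str(path)
        self._conn = sqlite3.connect(self.path)
        self._conn.row_factory = sqlite3.Row
        self._conn.executescript(_SCHEMA)
        self._conn.commit()

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "LesionStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # ------------------------------------------------------------------
    # hierarchy

    def upsert_hierarchy(self, volume: ImageVolume) -> dict:
        """Idempotently ensure patient/study/series rows for a volume.

        Repeat ingestion of the same series changes nothing.  A study or
        series UID already registered under a different parent is a
        collision and is rejected.
        """
        cur = self._conn.cursor()
        row = cur.execute(
            "SELECT patient_id FROM study WHERE study_uid=?", (volume.study_uid,)
        ).fetchone()
        if row is not None and row["patient_id"] != volume.patient_id:
            raise StoreError(
                f"study UID {volume.study_uid} already belongs to patient "
                f"{row['patient_id']}, not {volume.patient_id}"
            )
        row = cur.execute(
            "SELECT study_uid FROM series WHERE series_uid=?", (volume.series_uid,)
        ).fetchone()
        if row is not None and row["study_uid"] != volume.study_uid:
            raise StoreError(
                f"series UID {volume.series_uid} already belongs to study {row['study_uid']}"
            )
        cur.execute(
            "INSERT OR IGNORE INTO patient (patient_id) VALUES (?)", (volume.patient_id,)
        )
        cur.execute(
            "INSERT OR IGNORE INTO study (study_uid, patient_id, study_date) VALUES (?,?,?)",
            (volume.study_uid, volume.patient_id, volume.acquisition_date),
        )
        cur.execute(
            "INSERT OR IGNORE INTO series (series_uid, study_uid, modality, geometry_json)"
            " VALUES (?,?,?,?)",
            (volume.series_uid, volume.study_uid, volume.modality,
             _geometry_to_json(volume.geometry)),
        )
        self._conn.commit()
        return {
            "patient_id": volume.patient_id,
            "study_uid": volume.study_uid,
            "series_uid": volume.series_uid,
        }

    def add_user(self, user_id: str, display_name: str = "") -> None:
        self._conn.execute(
            "INSERT OR IGNORE INTO user (user_id, display_name) VALUES (?,?)",
            (user_id, display_name),
        )
        self._conn.commit()

    def series_geometry(self, series_uid: str) -> ImageGeometry:
        row = self._conn.execute(
            "SELECT geometry_json FROM series WHERE series_uid=?", (series_uid,)
        ).fetchone()
        if row is None:
            raise StoreError(f"unknown series {series_uid}")
        return _geometry_from_json(row["geometry_json"])

    # ------------------------------------------------------------------
    # lesions

    def save_lesion(
        self, mask: LesionMask, measurement: MeasurementRecord, user_id: str
    ) -> int:
        """Store a mask (DEFLATE-compressed) with its measurements.

        Requires existing series and user rows; replaces any previous
        row of the same (series, user, label) and updates ``modified``.
        Returns the lesion row id.
        """
        cur = self._conn.cursor()
        if cur.execute(
            "SELECT 1 FROM series WHERE series_uid=?", (mask.series_uid,)
        ).fetchone() is None:
            raise StoreError(f"unknown series_uid {mask.series_uid!r} (ingest the study first)")
        if cur.execute("SELECT 1 FROM user WHERE user_id=?", (user_id,)).fetchone() is None:
            raise StoreError(f"unknown user_id {user_id!r} (register the reader first)")

        comp = compress_mask(mask)
        label = mask.lesion_id or measurement.lesion_id
        now = _dt.datetime.now().isoformat(timespec="seconds")
        existing = cur.execute(
            "SELECT lesion_id, created FROM lesion WHERE series_uid=? AND user_id=? "
            "AND lesion_label=?",
            (mask.series_uid, user_id, label),
        ).fetchone()
        created = existing["created"] if existing else now
        if existing:
            cur.execute("DELETE FROM lesion WHERE lesion_id=?", (existing["lesion_id"],))
        cur.execute(
            "INSERT INTO lesion (series_uid, user_id, lesion_label, organ_label, payload,"
            " n_cols, n_rows, n_slices, geometry_digest, timepoint, unidimensional_mm,"
            " bidimensional_mm2, volume_mm3, diameter_slice, perpendicular_width_mm,"
            " created, modified) VALUES (?,?,?,?,?,?,?,?,?,?,?,?,?,?,?,?,?)",
            (
                mask.series_uid, user_id, label, mask.organ_label, comp.payload,
                *comp.dims, comp.geometry_digest, measurement.timepoint,
                measurement.unidimensional, measurement.bidimensional,
                measurement.volume, measurement.diameter_slice,
                measurement.perpendicular_width, created, now,
            ),
        )
        self._conn.commit()
        return int(cur.lastrowid)

    def _row_to_lesion(self, row: sqlite3.Row) -> tuple[LesionMask, MeasurementRecord]:
        g = self.series_geometry(row["series_uid"])
        comp = CompressedMask(
            payload=row["payload"],
            dims=(row["n_cols"], row["n_rows"], row["n_slices"]),
            geometry_digest=row["geometry_digest"],
            lesion_id=row["lesion_label"],
        )
        mask = decompress_mask(
            comp, g,
            series_uid=row["series_uid"], user_id=row["user_id"],
            organ_label=row["organ_label"],
        )
        rec = MeasurementRecord(
            lesion_id=row["lesion_label"],
            timepoint=row["timepoint"],
            unidimensional=row["unidimensional_mm"],
            bidimensional=row["bidimensional_mm2"],
            volume=row["volume_mm3"],
            diameter_slice=row["diameter_slice"],
            perpendicular_width=row["perpendicular_width_mm"],
        )
        return mask, rec

    def load_lesions(
        self,
        patient_id: str | None = None,
        study_uid: str | None = None,
        series_uid: str | None = None,
        user_id: str | None = None,
    ) -> list[tuple[LesionMask, MeasurementRecord]]:
        """Decompressed lesions matching the filter, deterministically ordered
        by (series_uid, lesion_label, user_id)."""
        query = (
            "SELECT lesion.* FROM lesion"
            " JOIN series ON lesion.series_uid = series.series_uid"
            " JOIN study ON series.study_uid = study.study_uid"
        )
        clauses, params = [], []
        if patient_id is not None:
            clauses.append("study.patient_id=?")
            params.append(patient_id)
        if study_uid is not None:
            clauses.append("study.study_uid=?")
            params.append(study_uid)
        if series_uid is not None:
            clauses.append("lesion.series_uid=?")
            params.append(series_uid)
        if user_id is not None:
            clauses.append("lesion.user_id=?")
            params.append(user_id)
        if clauses:
            query += " WHERE " + " AND ".join(clauses)
        query += " ORDER BY lesion.series_uid, lesion.lesion_label, lesion.user_id"
        rows = self._conn.execute(query, params).fetchall()
        return [self._row_to_lesion(r) for r in rows]

    # ------------------------------------------------------------------
    # queries and maintenance

    def patients(self) -> list[str]:
        return [r["patient_id"] for r in
                self._conn.execute("SELECT patient_id FROM patient ORDER BY patient_id")]

    def studies(self, patient_id: str) -> list[dict]:
        """Studies of one patient ordered by date (then UID): the timeline."""
        rows = self._conn.execute(
            "SELECT study_uid, study_date FROM study WHERE patient_id=?"
            " ORDER BY study_date, study_uid",
            (patient_id,),
        ).fetchall()
        return [dict(r) for r in rows]

    def series_of_study(self, study_uid: str) -> list[str]:
        return [r["series_uid"] for r in self._conn.execute(
            "SELECT series_uid FROM series WHERE study_uid=? ORDER BY series_uid",
            (study_uid,),
        )]

    def counts(self) -> dict:
        out = {}
        for table in ("patient", "study", "series", "user", "lesion"):
            out[table] = self._conn.execute(f"SELECT COUNT(*) c FROM {table}").fetchone()["c"]
        return out

    def lesion_table(self) -> pd.DataFrame:
        """Full lesion table (without blobs) for CSV export."""
        return pd.read_sql_query(
            "SELECT lesion_id, series_uid, user_id, lesion_label, organ_label, timepoint,"
            " unidimensional_mm, bidimensional_mm2, volume_mm3, diameter_slice,"
            " perpendicular_width_mm, created, modified FROM lesion"
            " ORDER BY series_uid, lesion_label, user_id",
            self._conn,
        )

    def integrity_check(self) -> IntegrityReport:
        """Verify foreign keys, payload decompressibility and uniqueness."""
        report = IntegrityReport()
        cur = self._conn.cursor()
        for row in cur.execute(
            "SELECT study_uid FROM study WHERE patient_id NOT IN (SELECT patient_id FROM patient)"
        ):
            report.findings.append(f"orphan study {row['study_uid']}")
        for row in cur.execute(
            "SELECT series_uid FROM series WHERE study_uid NOT IN (SELECT study_uid FROM study)"
        ):
            report.findings.append(f"orphan series {row['series_uid']}")
        for row in cur.execute(
            "SELECT lesion_id, series_uid, user_id FROM lesion WHERE series_uid NOT IN "
            "(SELECT series_uid FROM series) OR user_id NOT IN (SELECT user_id FROM user)"
        ):
            report.findings.append(f"lesion {row['lesion_id']}: dangling foreign key")
        for row in cur.execute("SELECT * FROM lesion"):
            try:
                self._row_to_lesion(row)
            except (MaskError, StoreError) as exc:
                report.findings.append(f"lesion {row['lesion_id']}: {exc}")
        dup = cur.execute(
            "SELECT series_uid, user_id, lesion_label, COUNT(*) c FROM lesion"
            " GROUP BY series_uid, user_id, lesion_label HAVING c > 1"
        ).fetchall()
        for row in dup:
            report.findings.append(
                f"duplicate lesion rows for ({row['series_uid']}, {row['user_id']}, "
                f"{row['lesion_label']})"
            )
        return report
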