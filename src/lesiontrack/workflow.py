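"""Patient-level assessment workflow: measure -> QA match -> classify.

Glues the stores, measurements, matching and response criteria into the
end-to-end pipeline a trial reader runs per patient: load the stored
lesions of every study on the patient's timeline, verify by positional
matching that the target lesions correspond across time points, then
summarise each time point and classify every follow-up under the
requested criteria.

A lesion whose follow-up mask is empty has vanished (it contributes 0
to every burden sum); vanished lesions are excluded from centroid
matching rather than counted as unmatched, otherwise every complete
response would fail QA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .db import LesionStore
from .matching import QAReport, lesion_centroid, match_lesions, qa_report
from .measure import TimepointSummary, timepoint_summary
from .response import ResponseLabel, best_overall_response, classify

__all__ = ["QAError", "PatientAssessment", "match_patient", "assess_patient"]


class QAError(RuntimeError):
    """Raised when target-lesion matching fails; carries the QA reports."""

    def __init__(self, message: str, reports: list[QAReport]):
        super().__init__(message)
        self.reports = reports


@dataclass
class PatientAssessment:
    patient_id: str
    summaries: list[TimepointSummary]
    labels: dict[int, list[ResponseLabel]]  # follow-up ordinal -> labels
    qa_reports: list[QAReport]
    best_overall: dict[str, str] = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        rows = []
        for t, summary in enumerate(self.summaries):
            base = {
                "timepoint_index": t,
                "date": summary.timepoint,
                "n_lesions": summary.n_lesions,
                "SLD_mm": summary.SLD,
                "SPD_mm2": summary.SPD,
                "volume_mm3": summary.total_volume,
            }
            if t == 0:
                rows.append({**base, "criterion": "", "category": "baseline",
                             "pct_from_baseline": 0.0, "pct_from_nadir": 0.0})
            else:
                for label in self.labels[t]:
                    rows.append(
                        {
                            **base,
                            "criterion": label.criterion,
                            "category": label.category,
                            "pct_from_baseline": label.pct_change_from_baseline,
                            "pct_from_nadir": label.pct_change_from_nadir,
                        }
                    )
        return pd.DataFrame(rows)


def _timepoint_lesions(store: LesionStore, patient_id: str, user_id: str | None):
    """Per-study (date-ordered) lesion lists for a patient."""
    studies = store.studies(patient_id)
    out = []
    for study in studies:
        lesions = store.load_lesions(
            patient_id=patient_id, study_uid=study["study_uid"], user_id=user_id
        )
        out.append((study, lesions))
    return out


def match_patient(
    store: LesionStore,
    patient_id: str,
    threshold: float = 50.0,
    user_id: str | None = None,
) -> list[QAReport]:
    """QA reports: baseline lesions vs each follow-up's, by position.

    Empty (vanished) masks are excluded from matching on either side.
    """
    timeline = _timepoint_lesions(store, patient_id, user_id)
    if len(timeline) < 2:
        raise ValueError(
            f"patient {patient_id}: need a baseline and at least one follow-up "
            f"(found {len(timeline)} studies)"
        )
    (_, baseline_lesions) = timeline[0]

    def centroids(lesions):
        pts, ids = [], []
        for mask, _rec in lesions:
            if not mask.is_empty():
                pts.append(lesion_centroid(mask))
                ids.append(mask.lesion_id)
        return pts, ids

    b_pts, b_ids = centroids(baseline_lesions)
    reports = []
    for _study, lesions in timeline[1:]:
        f_pts, f_ids = centroids(lesions)
        if not b_pts or not f_pts:
            # nothing measurable on one side: trivially consistent
            reports.append(QAReport(passed=True, rows=[]))
            continue
        match = match_lesions(b_pts, f_pts, threshold=threshold,
                              baseline_ids=b_ids, followup_ids=f_ids)
        reports.append(qa_report(match))
    return reports


def assess_patient(
    store: LesionStore,
    patient_id: str,
    criteria: tuple[str, ...] = ("RECIST", "WHO", "VOLUME"),
    match_threshold: float = 50.0,
    user_id: str | None = None,
) -> PatientAssessment:
    """Full response assessment for one patient.

    Refuses to classify when QA matching fails (raises :class:`QAError`
    pointing at the failing report).  Requires a baseline study with
    positive burden and at least one follow-up.
    """
    reports = match_patient(store, patient_id, threshold=match_threshold,
                            user_id=user_id)
    failed = [i for i, r in enumerate(reports, start=1) if not r.passed]
    if failed:
        raise QAError(
            f"patient {patient_id}: target-lesion matching failed at follow-up(s) "
            f"{failed}; inspect the QA report before assessing",
            reports,
        )

    timeline = _timepoint_lesions(store, patient_id, user_id)
    summaries = []
    for study, lesions in timeline:
        records = [rec for _mask, rec in lesions]
        for rec in records:
            rec.timepoint = study["study_date"]
        summary = timepoint_summary(records) if records else TimepointSummary(
            timepoint=study["study_date"]
        )
        summary.timepoint = study["study_date"]
        summaries.append(summary)

    baseline, followups = summaries[0], summaries[1:]
    labels: dict[int, list[ResponseLabel]] = {}
    for t, current in enumerate(followups, start=1):
        labels[t] = [
            classify(crit, baseline, followups[: t - 1], current) for crit in criteria
        ]
    best = {
        crit: best_overall_response(
            lab for labs in labels.values() for lab in labs if lab.criterion == crit.upper()
        )
        for crit in criteria
    }
    return PatientAssessment(
        patient_id=patient_id,
        summaries=summaries,
        labels=labels,
        qa_reports=reports,
        best_overall=best,
    )
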