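"""Cross-timepoint target-lesion matching (quality assurance step).

Target lesions selected at baseline must be paired with the same
physical lesions at each follow-up scan before burden sums are compared.
Matching uses the lesions' relative positions in the patient coordinate
system: both centroid sets are centred (their means subtracted, which
cancels global patient repositioning between scans), then a one-to-one
assignment minimising total squared distance is computed.  Pairs whose
residual distance exceeds a threshold are demoted to unmatched.

Rotation between time points is not corrected: CT patients are supine,
and the residual threshold absorbs small rotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .mask import LesionMask

__all__ = [
    "MatchResult",
    "QAReport",
    "DEFAULT_MATCH_THRESHOLD_MM",
    "lesion_centroid",
    "match_lesions",
    "qa_report",
]

#: default residual acceptance threshold: larger than typical couch
#: repositioning, smaller than typical inter-lesion spacing
DEFAULT_MATCH_THRESHOLD_MM = 50.0


@dataclass
class MatchResult:
    pairs: list[tuple[str, str]]  # (baseline id, follow-up id)
    residuals: list[float]  # mm, per pair, after centering
    unmatched_baseline: list[str]
    unmatched_followup: list[str]
    threshold: float = DEFAULT_MATCH_THRESHOLD_MM


def lesion_centroid(m: LesionMask) -> np.ndarray:
    """Mean patient-coordinate position (mm) of the foreground voxels."""
    if m.is_empty():
        raise ValueError(f"lesion {m.lesion_id or '<unnamed>'}: empty mask has no centroid")
    idx = np.argwhere(m.voxels)  # (slice, row, col)
    mean_ijk = idx[:, ::-1].mean(axis=0)  # -> (col, row, slice)
    # voxel->patient is affine, so mapping the mean index equals the
    # mean of the mapped voxel centres
    return m.geometry.voxel_to_patient(mean_ijk)


def match_lesions(
    baseline: np.ndarray | list,
    followup: np.ndarray | list,
    threshold: float = DEFAULT_MATCH_THRESHOLD_MM,
    baseline_ids: list[str] | None = None,
    followup_ids: list[str] | None = None,
) -> MatchResult:
    """Optimal one-to-one centroid assignment after centering.

    ``baseline`` and ``followup`` are lists of 3-vector centroids in
    patient mm.  Residuals are Euclidean distances between centred
    centroids; any pair with residual above ``threshold`` (mm) is
    demoted to unmatched.  Ids default to list indices as strings.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    b = np.atleast_2d(np.asarray(baseline, dtype=float))
    f = np.atleast_2d(np.asarray(followup, dtype=float))
    if baseline_ids is None:
        baseline_ids = [str(i) for i in range(len(b))]
    if followup_ids is None:
        followup_ids = [str(i) for i in range(len(f))]
    if len(b) == 0 or len(f) == 0:
        return MatchResult([], [], list(baseline_ids), list(followup_ids), threshold)

    bc = b - b.mean(axis=0)
    fc = f - f.mean(axis=0)
    dist = np.linalg.norm(bc[:, None, :] - fc[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(dist**2)

    pairs, residuals = [], []
    matched_b, matched_f = set(), set()
    for r, c in zip(rows, cols):
        if dist[r, c] <= threshold:
            pairs.append((baseline_ids[r], followup_ids[c]))
            residuals.append(float(dist[r, c]))
            matched_b.add(r)
            matched_f.add(c)
    return MatchResult(
        pairs=pairs,
        residuals=residuals,
        unmatched_baseline=[baseline_ids[i] for i in range(len(b)) if i not in matched_b],
        unmatched_followup=[followup_ids[i] for i in range(len(f)) if i not in matched_f],
        threshold=threshold,
    )


@dataclass
class QAReport:
    passed: bool
    rows: list[dict] = field(default_factory=list)

    def __str__(self) -> str:
        lines = [f"QA {'PASS' if self.passed else 'FAIL'}"]
        lines.append(f"{'baseline':<16}{'follow-up':<16}{'residual_mm':>12}  status")
        for row in self.rows:
            lines.append(
                f"{row['baseline_id'] or '-':<16}{row['followup_id'] or '-':<16}"
                f"{row['residual_mm'] if row['residual_mm'] is not None else '':>12}"
                f"  {row['status']}"
            )
        return "\n".join(lines)


def qa_report(match: MatchResult) -> QAReport:
    """Tabulate a match result; fails iff any lesion is unmatched."""
    rows = []
    for (bid, fid), res in zip(match.pairs, match.residuals):
        rows.append(
            {
                "baseline_id": bid,
                "followup_id": fid,
                "residual_mm": round(res, 3),
                "status": "matched",
            }
        )
    for bid in match.unmatched_baseline:
        rows.append(
            {"baseline_id": bid, "followup_id": None, "residual_mm": None,
             "status": "unmatched_baseline"}
        )
    for fid in match.unmatched_followup:
        rows.append(
            {"baseline_id": None, "followup_id": fid, "residual_mm": None,
             "status": "unmatched_followup"}
        )
    passed = not match.unmatched_baseline and not match.unmatched_followup
    return QAReport(passed=passed, rows=rows)
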