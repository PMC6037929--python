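"""Longitudinal response classification: RECIST, WHO and volumetry.

Each criterion reduces the per-timepoint tumor burden to one scalar and
classifies every follow-up against two references:

* the **baseline** scan, for response (PR/CR), and
* the **nadir** — the smallest burden over baseline and all earlier
  follow-ups — for progression (PD).

Rules (target lesions only):

========== ================ =============== ==========================
criterion  burden scalar    PR (vs baseline) PD (vs nadir)
========== ================ =============== ==========================
RECIST     SLD, mm          <= -30%          >= +20% and >= +5 mm abs
WHO        SPD, mm^2        <= -50%          >= +25%
VOLUME     volume, mm^3     <= -65.7%        >= +72.8%
========== ================ =============== ==========================

CR requires the burden to reach zero; anything else is SD.  The default
volumetric cutoffs are the RECIST diameter ratios cubed
(100*(0.7^3 - 1) and 100*(1.2^3 - 1)), i.e. the change a sphere shows
when its diameter crosses the RECIST boundaries; they are configurable.
RECIST follows the 1.1 semantics (nadir-referenced PD with the 5 mm
absolute guard); disabling the guard gives 1.0 behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .measure import TimepointSummary

__all__ = [
    "ResponseLabel",
    "Criterion",
    "CATEGORIES",
    "percent_change",
    "classify_recist",
    "classify_who",
    "classify_volumetric",
    "classify",
    "best_overall_response",
    "VOLUMETRIC_PR_PCT",
    "VOLUMETRIC_PD_PCT",
]

CATEGORIES = ("CR", "PR", "SD", "PD")  # best-to-worst ordering
CRITERIA = ("RECIST", "WHO", "VOLUME")

VOLUMETRIC_PR_PCT = 100.0 * (0.7**3 - 1.0)  # -65.7
VOLUMETRIC_PD_PCT = 100.0 * (1.2**3 - 1.0)  # +72.8


@dataclass
class ResponseLabel:
    criterion: str
    category: str
    pct_change_from_baseline: float
    pct_change_from_nadir: float
    reference_timepoint: int  # ordinal of the nadir timepoint used for PD

    def as_dict(self) -> dict:
        return {
            "criterion": self.criterion,
            "category": self.category,
            "pct_from_baseline": self.pct_change_from_baseline,
            "pct_from_nadir": self.pct_change_from_nadir,
            "nadir_timepoint": self.reference_timepoint,
        }


@dataclass
class Criterion:
    """A named response criterion on one burden scalar."""

    name: str
    attr: str  # TimepointSummary attribute holding the burden
    pr_pct: float  # response threshold vs baseline (negative)
    pd_pct: float  # progression threshold vs nadir (positive)
    pd_abs_guard: float = 0.0  # minimum absolute increase for PD, same units

    def __post_init__(self) -> None:
        if self.pr_pct >= 0 or self.pd_pct <= 0:
            raise ValueError("PR threshold must be negative and PD threshold positive")


def percent_change(reference: float, current: float) -> float:
    """100 * (current - reference) / reference; reference must be > 0."""
    if reference <= 0:
        raise ValueError("percent change needs a positive reference (new growth "
                         "from zero has no defined percentage)")
    return 100.0 * (current - reference) / reference


def _classify(
    crit: Criterion,
    baseline: TimepointSummary,
    history: Sequence[TimepointSummary],
    current: TimepointSummary,
) -> ResponseLabel:
    base = float(getattr(baseline, crit.attr))
    if base <= 0:
        raise ValueError(f"{crit.name}: baseline burden must be positive")
    cur = float(getattr(current, crit.attr))

    prior = [base] + [float(getattr(s, crit.attr)) for s in history]
    nadir = min(prior)
    nadir_tp = int(prior.index(nadir))  # 0 = baseline, i = i-th follow-up

    pct_base = percent_change(base, cur)
    pct_nadir = percent_change(nadir, cur) if nadir > 0 else (0.0 if cur == 0 else float("inf"))

    if cur == 0:
        category = "CR"
    elif pct_nadir >= crit.pd_pct and (cur - nadir) >= crit.pd_abs_guard:
        category = "PD"
    elif pct_base <= crit.pr_pct:
        category = "PR"
    else:
        category = "SD"
    return ResponseLabel(
        criterion=crit.name,
        category=category,
        pct_change_from_baseline=pct_base,
        pct_change_from_nadir=pct_nadir,
        reference_timepoint=nadir_tp,
    )


def classify_recist(
    baseline: TimepointSummary,
    history: Sequence[TimepointSummary],
    current: TimepointSummary,
    absolute_guard_mm: float = 5.0,
) -> ResponseLabel:
    """RECIST 1.1 on the sum of longest diameters (set guard to 0 for 1.0)."""
    crit = Criterion("RECIST", "SLD", pr_pct=-30.0, pd_pct=20.0,
                     pd_abs_guard=absolute_guard_mm)
    return _classify(crit, baseline, history, current)


def classify_who(
    baseline: TimepointSummary,
    history: Sequence[TimepointSummary],
    current: TimepointSummary,
) -> ResponseLabel:
    """WHO bidimensional criteria on the sum of perpendicular products."""
    crit = Criterion("WHO", "SPD", pr_pct=-50.0, pd_pct=25.0)
    return _classify(crit, baseline, history, current)


def classify_volumetric(
    baseline: TimepointSummary,
    history: Sequence[TimepointSummary],
    current: TimepointSummary,
    pr_pct: float = VOLUMETRIC_PR_PCT,
    pd_pct: float = VOLUMETRIC_PD_PCT,
) -> ResponseLabel:
    """Volumetric criteria on total tumor volume, configurable cutoffs."""
    crit = Criterion("VOLUME", "total_volume", pr_pct=pr_pct, pd_pct=pd_pct)
    return _classify(crit, baseline, history, current)


_CLASSIFIERS = {
    "RECIST": classify_recist,
    "WHO": classify_who,
    "VOLUME": classify_volumetric,
}


def classify(
    criterion: str,
    baseline: TimepointSummary,
    history: Sequence[TimepointSummary],
    current: TimepointSummary,
    **options,
) -> ResponseLabel:
    try:
        fn = _CLASSIFIERS[criterion.upper()]
    except KeyError:
        raise ValueError(f"unknown criterion {criterion!r}; choose from {CRITERIA}")
    return fn(baseline, history, current, **options)


def best_overall_response(labels: Iterable[ResponseLabel]) -> str:
    """Best category achieved across timepoints (CR > PR > SD > PD)."""
    cats = [lab.category for lab in labels]
    if not cats:
        raise ValueError("no response labels to summarize")
    return min(cats, key=CATEGORIES.index)
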