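"""Graded toxicity records and their dichotomization into event labels.

Two utilization methods are compared throughout the package:

* ``uncorrected`` — event iff the maximum of the 12- and 24-month grades is
  >= the cutpoint (default grade 1), ignoring the baseline grade;
* ``baseline_corrected`` — event iff (max follow-up grade - baseline grade)
  >= the cutpoint.  Negative adjusted values map to non-event.

Because subtracting a non-negative baseline can only lower the adjusted
score, a corrected event implies an uncorrected one, so corrected event
counts never exceed uncorrected counts on any cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .conventions import MissingDataError

__all__ = [
    "ENDPOINTS",
    "METHODS",
    "ToxicityRecord",
    "OutcomeLabel",
    "dichotomize_uncorrected",
    "dichotomize_corrected",
    "label_cohort",
    "split_cohort",
    "labels_to_frame",
]

#: The 17 clinician-graded late endpoints (CTCAE grades 0-3).
ENDPOINTS = (
    "proctitis",
    "perforation",
    "bowel_obstruction",
    "fistula",
    "bowel_stenosis",
    "bowel_ulceration",
    "diarrhoea",
    "flatus",
    "rectal_bleeding",
    "sphincter_control",
    "haematuria",
    "urinary_tract_obstruction",
    "urinary_incontinence",
    "urinary_frequency",
    "urinary_urgency",
    "urinary_retention",
    "bowel_fistula",
)

METHODS = ("uncorrected", "baseline_corrected")

_GRADES = (0, 1, 2, 3)


@dataclass(frozen=True)
class ToxicityRecord:
    """Per-patient grades for one endpoint at baseline, 12 and 24 months.

    Missing assessments are ``None``.
    """

    endpoint: str
    grade_baseline: int | None
    grade_12m: int | None
    grade_24m: int | None
    patient_id: int | None = None

    def __post_init__(self) -> None:
        for g in (self.grade_baseline, self.grade_12m, self.grade_24m):
            if g is not None and g not in _GRADES:
                raise ValueError(f"grade {g!r} outside {{0,1,2,3}}")


@dataclass(frozen=True)
class OutcomeLabel:
    patient_id: int | None
    endpoint: str
    method: str
    event: int

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


def _max_followup(rec: ToxicityRecord) -> int:
    grades = [g for g in (rec.grade_12m, rec.grade_24m) if g is not None]
    if not grades:
        raise MissingDataError(
            f"patient {rec.patient_id}, endpoint {rec.endpoint}: "
            "both follow-up grades missing")
    return max(grades)


def dichotomize_uncorrected(rec: ToxicityRecord, cutpoint: int = 1) -> OutcomeLabel:
    """Event iff max(12m, 24m) grade >= cutpoint; baseline ignored."""
    event = int(_max_followup(rec) >= cutpoint)
    return OutcomeLabel(rec.patient_id, rec.endpoint, "uncorrected", event)


def dichotomize_corrected(rec: ToxicityRecord, cutpoint: int = 1) -> OutcomeLabel:
    """Event iff max(12m, 24m) grade minus baseline grade >= cutpoint.

    Negative adjusted scores count as non-event.  Raises
    :class:`MissingDataError` if the baseline (or every follow-up) grade is
    absent — such patients are excluded for this endpoint under this method
    only.
    """
    if rec.grade_baseline is None:
        raise MissingDataError(
            f"patient {rec.patient_id}, endpoint {rec.endpoint}: "
            "baseline grade missing")
    adjusted = _max_followup(rec) - rec.grade_baseline
    event = int(adjusted >= cutpoint)
    return OutcomeLabel(rec.patient_id, rec.endpoint, "baseline_corrected", event)


def label_cohort(records: Iterable[ToxicityRecord], method: str,
                 cutpoint: int = 1) -> tuple[list[OutcomeLabel], list[ToxicityRecord]]:
    """Dichotomize a cohort, collecting (labels, excluded records).

    Exclusions (missing required grades) are returned, never silently
    dropped; the two methods may analyse different denominators.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    fn = dichotomize_uncorrected if method == "uncorrected" else dichotomize_corrected
    labels, excluded = [], []
    for rec in records:
        try:
            labels.append(fn(rec, cutpoint=cutpoint))
        except MissingDataError:
            excluded.append(rec)
    return labels, excluded


def split_cohort(dsms: Sequence, labels: Sequence[OutcomeLabel]):
    """Partition DSMs into (event, non-event) collections, one label each."""
    if len(dsms) != len(labels):
        raise ValueError("need exactly one label per DSM")
    event = [d for d, l in zip(dsms, labels) if l.event == 1]
    nonevent = [d for d, l in zip(dsms, labels) if l.event == 0]
    return event, nonevent


def labels_to_frame(labels: Iterable[OutcomeLabel]) -> pd.DataFrame:
    """Export labels as a tidy table (patient_id, endpoint, method, event)."""
    return pd.DataFrame(
        [(l.patient_id, l.endpoint, l.method, l.event) for l in labels],
        columns=["patient_id", "endpoint", "method", "event"],
    )
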