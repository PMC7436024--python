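"""Modified Iowa Level of Assistance Scale (mILAS) scoring.

The scale rates the assistance a patient needs for five activities of
daily living — supine-to-sit transfer, sit-to-supine transfer,
sit-to-stand, walking, and stair climbing — each on 0 (independent) to
6 points, for a total of 0-30.  Stair climbing is assessed only when
the patient has stairs at home; otherwise the item is scored zero.
Functional recovery means a total score of zero; the study endpoint is
whether that happens on or before the first postoperative day.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import pandas as pd

from .errors import InputError, MilasValidationError

ITEMS = ("supine_to_sit", "sit_to_supine", "sit_to_stand", "walking", "stairs")
MAX_ITEM = 6
MAX_TOTAL = MAX_ITEM * len(ITEMS)


@dataclass(frozen=True)
class MilasAssessment:
    """One scored assessment, normally entered by the physiotherapist."""

    patient_id: str
    timestamp: pd.Timestamp
    items: dict = field(default_factory=dict)
    needs_stairs_at_home: bool = True

    def __post_init__(self):
        unknown = set(self.items) - set(ITEMS)
        if unknown:
            raise MilasValidationError(f"unknown items {sorted(unknown)}")


def _validated_items(items: dict, needs_stairs_at_home: bool) -> dict:
    out = {}
    for name in ITEMS:
        score = items.get(name, 0)
        if not float(score).is_integer() or not 0 <= int(score) <= MAX_ITEM:
            raise MilasValidationError(
                f"item {name!r} score {score!r} outside 0-{MAX_ITEM}"
            )
        out[name] = int(score)
    if not needs_stairs_at_home:
        out["stairs"] = 0  # the stairs rule: not assessed, scored zero
    return out


def total_score(assessment: MilasAssessment) -> int:
    """Sum of the five item scores after applying the stairs rule."""
    items = _validated_items(assessment.items, assessment.needs_stairs_at_home)
    return sum(items.values())


def percentage_score(assessment: MilasAssessment) -> tuple[float, dict]:
    """Percentage transforms: 100% means complete independence.

    Overall score is the linear complement ``(30 - total) / 30 * 100``;
    each activity gets the analogous ``(6 - item) / 6 * 100`` so the
    display can show which activities still hold recovery back.
    """
    items = _validated_items(assessment.items, assessment.needs_stairs_at_home)
    total = sum(items.values())
    overall = (MAX_TOTAL - total) / MAX_TOTAL * 100.0
    per_activity = {k: (MAX_ITEM - v) / MAX_ITEM * 100.0 for k, v in items.items()}
    return overall, per_activity


def assessments_frame(assessments: list[MilasAssessment]) -> pd.DataFrame:
    """Tabular view of a list of assessments, one row each, with totals."""
    rows = []
    for a in assessments:
        items = _validated_items(a.items, a.needs_stairs_at_home)
        rows.append(
            {
                "patient_id": a.patient_id,
                "timestamp": pd.Timestamp(a.timestamp),
                **items,
                "needs_stairs_at_home": a.needs_stairs_at_home,
                "total": sum(items.values()),
            }
        )
    return pd.DataFrame(rows)


def recovery_endpoint(
    milas: pd.DataFrame, surgery_dates: dict | pd.Series
) -> pd.DataFrame:
    """Dichotomized recovered-on-day-one endpoint per patient.

    ``milas`` is an assessment log (``patient_id, timestamp, total``
    at minimum); ``surgery_dates`` maps patient id to surgery date.
    Assessments can occur several times per day; the day's minimum total
    governs, since recovery is a ratchet in clinical use.  Returns one
    row per patient: ``first_zero_pod`` (postoperative-day index of the
    earliest zero total, <NA> if none) and ``recovered_on_pod1``
    (1 when the first zero falls on or before day one).
    """
    if milas.empty:
        raise InputError("empty assessment log")
    df = milas.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    surgery = pd.Series(surgery_dates)
    rows = []
    for pid, grp in df.groupby("patient_id", sort=True):
        if pid not in surgery.index:
            raise InputError(f"no surgery date for patient {pid!r}")
        sdate = pd.Timestamp(surgery[pid]).date()
        pods = grp["timestamp"].dt.date.map(lambda d: (d - sdate).days)
        day_min = grp.groupby(pods)["total"].min()
        zeros = day_min[day_min == 0]
        first_zero = int(zeros.index.min()) if len(zeros) else None
        rows.append(
            {
                "patient_id": pid,
                "first_zero_pod": first_zero,
                "recovered_on_pod1": int(first_zero is not None and first_zero <= 1),
            }
        )
    out = pd.DataFrame(rows)
    out["first_zero_pod"] = out["first_zero_pod"].astype("Int64")
    return out
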