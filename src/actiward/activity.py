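"""Daily activity summaries and the valid-day rule.

The primary outcome of the monitoring chain is the number of minutes
spent standing and walking per calendar day.  A day counts as a valid
measurement day only when the sensor covered at least 20 of its 24
hours; days below that threshold are excluded rather than zero-filled,
because absent data means the device was not worn, not that the patient
was sedentary.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigError, IndexingError, InputError

DAILY_COLUMNS = [
    "patient_id",
    "calendar_date",
    "pod_index",
    "wear_h",
    "valid",
    "active_min",
]


@dataclass(frozen=True)
class SummaryConfig:
    """Valid-day threshold (hours) and day-boundary convention.

    Days run midnight-to-midnight local time; the postoperative-day
    index counts calendar days since surgery with the surgery day as 0,
    so index 1 is the first full postoperative day.
    """

    valid_day_threshold_h: float = 20.0

    def __post_init__(self):
        if not 0 < self.valid_day_threshold_h <= 24:
            raise ConfigError("valid_day_threshold_h must lie in (0, 24]")


def summarize_days(
    minutes: pd.DataFrame,
    surgery_date: date,
    config: SummaryConfig = SummaryConfig(),
    patient_id: str = "",
) -> pd.DataFrame:
    """Aggregate minute records into per-calendar-day summaries.

    ``minutes`` is a minute-record frame (``minute_start, sedentary_s,
    standing_s, dynamic_s, covered_s``).  Wear time is the covered
    (classified) time — non-wear transmits nothing — and active minutes
    are the standing plus dynamic seconds over sixty.
    """
    if minutes.empty:
        raise InputError("no minute records to summarize")
    surgery_date = pd.Timestamp(surgery_date).date()
    df = minutes.copy()
    df["calendar_date"] = df["minute_start"].dt.date
    if df["calendar_date"].max() < surgery_date:
        raise IndexingError(
            f"surgery date {surgery_date} is after the last recorded day"
        )
    g = df.groupby("calendar_date")
    out = g.agg(
        covered_s=("covered_s", "sum"),
        active_s=("standing_s", "sum"),
        dynamic_s=("dynamic_s", "sum"),
    ).reset_index()
    out["wear_h"] = out["covered_s"] / 3600.0
    out["active_min"] = (out["active_s"] + out["dynamic_s"]) / 60.0
    out["valid"] = out["wear_h"] >= config.valid_day_threshold_h
    out["pod_index"] = out["calendar_date"].map(
        lambda d: (d - surgery_date).days
    )
    out["patient_id"] = patient_id
    return out[DAILY_COLUMNS]


def select_analysis_days(daily: pd.DataFrame, pod: int = 1) -> pd.Series:
    """Per-patient active minutes on one postoperative day, NaN if missing.

    Only valid measurement days qualify; a patient with no valid day at
    the requested index is reported missing (NaN), never zero-filled.
    The index covers every patient present in ``daily``.
    """
    if pod < 0:
        raise ConfigError("pod must be >= 0")
    patients = pd.Index(daily["patient_id"].unique(), name="patient_id")
    hits = daily[(daily["pod_index"] == pod) & daily["valid"]]
    # a patient can in principle have two valid records only through
    # duplicated input; keep the first deterministically
    series = hits.drop_duplicates("patient_id").set_index("patient_id")["active_min"]
    return series.reindex(patients).astype(float).rename(f"active_min_pod{pod}")


class DailyActivitySummarizer(TransformerMixin, BaseEstimator):
    """Minute records → daily summaries, as a scikit-learn transformer.

    Stateless apart from parameter validation in ``fit``; ``transform``
    expects the minute-record frame produced by the posture classifier.
    """

    def __init__(
        self,
        surgery_date: date | None = None,
        valid_day_threshold_h: float = 20.0,
        patient_id: str = "",
    ):
        self.surgery_date = surgery_date
        self.valid_day_threshold_h = valid_day_threshold_h
        self.patient_id = patient_id

    def fit(self, X: pd.DataFrame | None = None, y=None):
        if self.surgery_date is None:
            raise ConfigError("surgery_date is required")
        self.config_ = SummaryConfig(valid_day_threshold_h=self.valid_day_threshold_h)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self.fit()
        return summarize_days(
            X, self.surgery_date, self.config_, patient_id=self.patient_id
        )


def wear_consistency(daily: pd.DataFrame) -> bool:
    """Internal consistency: active minutes can never exceed wear time."""
    return bool(np.all(daily["active_min"] <= daily["wear_h"] * 60.0 + 1e-9))
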