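"""CSV interchange, pipeline configuration, accounting and reporting.

All tabular interchange is plain CSV with explicit headers and
ISO-8601 local timestamps.  Every writer here has a matching reader
and the pair round-trips losslessly; schema violations are reported by
column name before any computation starts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from datetime import date
from pathlib import Path

import pandas as pd
import yaml

from . import activity, analysis, milas, signal, simulate
from .errors import ConfigError, SchemaError, SingleClassError

log = logging.getLogger("actiward")

SCHEMAS = {
    "signal": ["timestamp", "x_g", "y_g", "z_g"],
    "schedule": ["patient_id", "start", "duration_s", "posture"],
    "patients": [
        "patient_id", "group", "age", "sex", "bmi", "surgery", "asa_class", "los_days",
    ],
    "minutes": ["minute_start", "sedentary_s", "standing_s", "dynamic_s", "covered_s"],
    "daily": activity.DAILY_COLUMNS,
    "milas": ["patient_id", "timestamp", *milas.ITEMS, "needs_stairs_at_home", "total"],
}

_TIME_COLS = {"timestamp", "minute_start", "start"}
_DATE_COLS = {"calendar_date"}


def _check_schema(df: pd.DataFrame, kind: str):
    missing = [c for c in SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise SchemaError(f"{kind} table is missing column(s) {missing}")


def write_table(df: pd.DataFrame, path: str | Path, kind: str):
    _check_schema(df, kind)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S.%f")


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_schema(df, kind)
    for col in df.columns:
        if col in _TIME_COLS:
            df[col] = pd.to_datetime(df[col])
        elif col in _DATE_COLS:
            df[col] = pd.to_datetime(df[col]).dt.date
    return df


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything one reproducible run needs, loadable from YAML.

    Unknown keys anywhere in the file are rejected so that a typo in a
    threshold name fails loudly instead of silently using a default.
    """

    seed: int = 0
    out_dir: str = "actiward_out"
    classifier: signal.ClassifierConfig = field(default_factory=signal.ClassifierConfig)
    summary: activity.SummaryConfig = field(default_factory=activity.SummaryConfig)
    sensor: simulate.SensorConfig = field(default_factory=simulate.SensorConfig)
    cohort: simulate.CohortParams = field(default_factory=simulate.CohortParams)
    analysis_pod: int = 1
    candidates: tuple = analysis.DEFAULT_CANDIDATES
    cie_threshold_pct: float = 10.0
    cie_reference: str = "current"


def _build_dataclass(cls, payload: dict, where: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(payload) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")
    return cls(**payload)


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a YAML pipeline configuration, rejecting unknown keys."""
    payload = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(payload, dict):
        raise ConfigError("configuration root must be a mapping")
    blocks = {
        "classifier": signal.ClassifierConfig,
        "summary": activity.SummaryConfig,
        "sensor": simulate.SensorConfig,
        "cohort": simulate.CohortParams,
    }
    kwargs = {}
    for key, value in payload.items():
        if key in blocks:
            if not isinstance(value, dict):
                raise ConfigError(f"block {key!r} must be a mapping")
            if key == "cohort" and "surgery_date" in value:
                value = {**value, "surgery_date": pd.Timestamp(value["surgery_date"]).date()}
            kwargs[key] = _build_dataclass(blocks[key], value, key)
        elif key in {f.name for f in fields(PipelineConfig)}:
            kwargs[key] = tuple(value) if key == "candidates" else value
        else:
            raise ConfigError(f"unknown top-level key {key!r}")
    return PipelineConfig(**kwargs)


# ---------------------------------------------------------------------------
# cohort accounting
# ---------------------------------------------------------------------------

@dataclass
class CohortAccounting:
    """Enrolment-to-analysis flow counts with self-consistent percentages."""

    n_enrolled: int
    exclusions: dict
    n_analyzed: int
    n_with_pod1: int

    @property
    def pct_analyzed(self) -> float:
        return 100.0 * self.n_analyzed / self.n_enrolled if self.n_enrolled else 0.0

    @property
    def pct_with_pod1(self) -> float:
        return 100.0 * self.n_with_pod1 / self.n_analyzed if self.n_analyzed else 0.0

    def __post_init__(self):
        if self.n_enrolled - sum(self.exclusions.values()) != self.n_analyzed:
            raise ConfigError("accounting does not balance: enrolled - excluded != analyzed")
        if self.n_with_pod1 > self.n_analyzed:
            raise ConfigError("more day-one records than analyzable patients")

    def to_text(self) -> str:
        lines = [f"Enrolled: {self.n_enrolled}"]
        for reason, n in sorted(self.exclusions.items()):
            lines.append(f"  excluded ({reason.replace('_', ' ')}): {n}")
        lines.append(f"Analyzed: {self.n_analyzed} ({self.pct_analyzed:.1f}%)")
        lines.append(
            f"With valid POD1 activity data: {self.n_with_pod1} ({self.pct_with_pod1:.0f}%)"
        )
        return "\n".join(lines)


def account_cohort(patients: pd.DataFrame, daily: pd.DataFrame) -> CohortAccounting:
    """Compute the enrolment flow from the data itself.

    A patient is analyzable when at least one valid measurement day
    exists; exclusion reasons come from the ``exclusion_reason`` column
    where present (``other`` otherwise).
    """
    _check_schema(daily, "daily")
    valid_days = daily[daily["valid"]].groupby("patient_id").size()
    has_valid = patients["patient_id"].map(valid_days).fillna(0) > 0
    excluded = patients.loc[~has_valid]
    reasons: dict[str, int] = {}
    for _, row in excluded.iterrows():
        reason = row.get("exclusion_reason", "") or "other"
        reasons[reason] = reasons.get(reason, 0) + 1
    analyzed_ids = set(patients.loc[has_valid, "patient_id"])
    pod1 = daily[(daily["pod_index"] == 1) & daily["valid"]]
    n_pod1 = pod1["patient_id"].isin(analyzed_ids).sum()
    return CohortAccounting(
        n_enrolled=len(patients),
        exclusions=reasons,
        n_analyzed=int(has_valid.sum()),
        n_with_pod1=int(n_pod1),
    )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _fit_to_frame(fit: analysis.ModelFit) -> pd.DataFrame:
    out = fit.table.copy()
    out.insert(0, "term", out.index)
    return out.reset_index(drop=True)


def analyze_cohort(
    patients: pd.DataFrame,
    daily: pd.DataFrame,
    milas_log: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> dict:
    """Run accounting, descriptives, both regressions and both selections.

    Returns a dict of result objects/frames; ``run_pipeline`` writes
    them to disk.  Raises a single-class error when either study arm is
    absent, since a group comparison is then undefined.
    """
    config = config or PipelineConfig()
    if patients["group"].nunique() < 2:
        raise SingleClassError("cohort contains a single study arm; cannot compare groups")
    accounting = account_cohort(patients, daily)

    pod_col = f"active_min_pod{config.analysis_pod}"
    active = activity.select_analysis_days(daily, pod=config.analysis_pod)
    cohort = patients.merge(
        active.rename(pod_col).reset_index(), on="patient_id", how="left"
    )
    surgery_dates = {
        pid: config.cohort.surgery_date for pid in patients["patient_id"]
    }
    recovery = milas.recovery_endpoint(milas_log, surgery_dates)
    cohort = cohort.merge(recovery, on="patient_id", how="left")
    if "asa_high" not in cohort.columns:
        cohort["asa_high"] = (cohort["asa_class"] == 3).astype(int)
    analyzed = cohort[cohort["patient_id"].map(
        daily[daily["valid"]].groupby("patient_id").size()
    ).fillna(0) > 0]

    log.info("accounting:\n%s", accounting.to_text())
    descriptives = analysis.describe(analyzed)

    uni_lin = analysis.fit_linear(analyzed, outcome=pod_col, predictors=["group"])
    sel_lin = analysis.ChangeInEstimateSelector(
        outcome=pod_col,
        candidates=tuple(config.candidates),
        model_type="linear",
        threshold_pct=config.cie_threshold_pct,
        reference=config.cie_reference,
    ).fit(analyzed)
    uni_log = analysis.fit_logistic(
        analyzed, outcome="recovered_on_pod1", predictors=["group"]
    )
    sel_log = analysis.ChangeInEstimateSelector(
        outcome="recovered_on_pod1",
        candidates=tuple(config.candidates),
        model_type="logistic",
        threshold_pct=config.cie_threshold_pct,
        reference=config.cie_reference,
    ).fit(analyzed)
    return {
        "accounting": accounting,
        "cohort": analyzed,
        "descriptives": descriptives,
        "linear_univariate": uni_lin,
        "linear_selection": sel_lin,
        "logistic_univariate": uni_log,
        "logistic_selection": sel_log,
    }


def _report_text(results: dict, config: PipelineConfig) -> str:
    def fmt_fit(title, fit: analysis.ModelFit):
        lines = [title, "-" * len(title)]
        lines.append(_fit_to_frame(fit).round(4).to_string(index=False))
        lines.append(f"n = {fit.n_used}")
        return "\n".join(lines)

    sel_lin = results["linear_selection"]
    sel_log = results["logistic_selection"]
    parts = [
        "actiward pipeline report",
        "========================",
        f"seed = {config.seed}",
        f"classifier = {config.classifier}",
        f"summary = {config.summary}",
        f"selection threshold = {config.cie_threshold_pct}% (reference: {config.cie_reference})",
        "",
        "Cohort accounting",
        "-----------------",
        results["accounting"].to_text(),
        "",
        "Descriptives (per arm)",
        "----------------------",
        results["descriptives"].to_string(index=False),
        "",
        fmt_fit("Univariate linear model (active minutes, day one)", results["linear_univariate"]),
        "",
        fmt_fit(
            f"Multiple linear model (selected: {sel_lin.selected_ or 'none'})",
            sel_lin.model_,
        ),
        "",
        fmt_fit("Univariate logistic model (recovered by day one)", results["logistic_univariate"]),
        "",
        fmt_fit(
            f"Multiple logistic model (selected: {sel_log.selected_ or 'none'})",
            sel_log.model_,
        ),
        "",
    ]
    return "\n".join(parts)


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate (or load), analyze, and write the full report.

    Deterministic given the configuration and seed: the same inputs
    produce byte-identical output files.
    """
    from dataclasses import replace

    params = replace(config.cohort, seed=config.seed)
    patients, daily, milas_log = simulate.simulate_study_flow(params, seed=config.seed)
    results = analyze_cohort(patients, daily, milas_log, config)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(patients, out / "patients.csv", "patients")
    write_table(daily, out / "daily.csv", "daily")
    write_table(milas_log, out / "milas.csv", "milas")
    results["descriptives"].to_csv(out / "descriptives.csv", index=False)
    for name in ("linear_univariate", "logistic_univariate"):
        _fit_to_frame(results[name]).to_csv(out / f"{name}.csv", index=False)
    for name in ("linear_selection", "logistic_selection"):
        sel = results[name]
        _fit_to_frame(sel.model_).to_csv(out / f"{name}_model.csv", index=False)
        sel.trace_.to_frame().to_csv(out / f"{name}_trace.csv", index=False)
    report = _report_text(results, config)
    (out / "report.txt").write_text(report)
    log.info("report written to %s", out / "report.txt")
    results["report_text"] = report
    return results
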