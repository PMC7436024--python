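"""Seeded generators for accelerometer signals and patient cohorts.

Two layers are generated independently:

* the **signal layer** — posture-bout schedules of a hospitalized
  arthroplasty patient and the corresponding raw 25 Hz tri-axial
  acceleration trace, used to exercise the posture classifier; and
* the **cohort layer** — covariate tables, per-day activity summaries
  and assistance-scale (mILAS) trajectories with a known group effect
  and a known confounding structure, used to exercise the regression
  and confounder-selection machinery.

All randomness flows from a single integer seed through one
:class:`numpy.random.Generator`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError, ScheduleError

POSTURES = ("lying", "sitting", "standing", "walking", "nonwear")
#: Postures during which the sensor is upright (thigh vertical).
UPRIGHT = ("standing", "walking")
#: Postures that transmit samples at all.
WORN = ("lying", "sitting", "standing", "walking")

EXCLUSION_RULES = ("delayed_fixation", "malfunction", "early_discharge", "other")


@dataclass(frozen=True)
class PostureBout:
    """One contiguous stretch of a single posture."""

    start: pd.Timestamp
    duration_s: float
    posture: str

    def __post_init__(self):
        if self.posture not in POSTURES:
            raise ScheduleError(f"unknown posture {self.posture!r}")
        if self.duration_s < 1:
            raise ScheduleError("bout duration must be >= 1 s")

    @property
    def end(self) -> pd.Timestamp:
        return self.start + pd.Timedelta(seconds=self.duration_s)


@dataclass(frozen=True)
class SensorConfig:
    """Physical model of the thigh-worn sensor.

    The longitudinal axis lies along the femur, so gravity projects
    fully onto it when the patient is upright and (ideally) not at all
    when the thigh is horizontal.  Walking superimposes a sinusoidal
    oscillation at the step frequency on the upright orientation.
    """

    sample_rate_hz: float = 25.0
    range_g: float = 8.0
    noise_sd_g: float = 0.03
    longitudinal_axis: str = "z"
    gait_freq_hz: float = 1.5
    gait_amp_g: float = 0.4

    def __post_init__(self):
        if self.sample_rate_hz <= 0:
            raise ConfigError("sample_rate_hz must be positive")
        if self.range_g <= 0:
            raise ConfigError("range_g must be positive")
        if self.noise_sd_g < 0:
            raise ConfigError("noise_sd_g must be >= 0")
        if self.longitudinal_axis not in ("x", "y", "z"):
            raise ConfigError("longitudinal_axis must be one of x, y, z")


def validate_schedule(schedule: list[PostureBout]) -> list[PostureBout]:
    """Check that bouts are time-ordered and non-overlapping."""
    bouts = sorted(schedule, key=lambda b: b.start)
    for prev, nxt in zip(bouts, bouts[1:]):
        if nxt.start < prev.end:
            raise ScheduleError(
                f"bouts overlap: {prev.posture} ending {prev.end} vs "
                f"{nxt.posture} starting {nxt.start}"
            )
    return bouts


def simulate_signal(
    schedule: list[PostureBout],
    config: SensorConfig = SensorConfig(),
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a raw tri-axial acceleration trace for a bout schedule.

    Returns a frame with columns ``timestamp, x_g, y_g, z_g`` sampled at
    ``config.sample_rate_hz`` within worn bouts; non-wear bouts transmit
    nothing.  Lying and sitting place gravity on an axis perpendicular
    to the thigh, standing places it on the longitudinal axis, and
    walking adds a ``gait_amp_g`` sinusoid at ``gait_freq_hz`` on top of
    the standing orientation.  Samples are clipped to ``±range_g``.
    """
    bouts = validate_schedule(schedule)
    rng = np.random.default_rng(seed)
    axes = ["x", "y", "z"]
    long_ax = config.longitudinal_axis
    # perpendicular axes used for the horizontal-gravity component
    perp = [a for a in axes if a != long_ax]
    frames = []
    for bout in bouts:
        if bout.posture == "nonwear":
            continue
        n = int(round(bout.duration_s * config.sample_rate_hz))
        if n == 0:
            continue
        rel_t = np.arange(n) / config.sample_rate_hz
        ts = bout.start + pd.to_timedelta(rel_t, unit="s")
        data = {a: np.zeros(n) for a in axes}
        if bout.posture in UPRIGHT:
            data[long_ax] = np.ones(n)
            if bout.posture == "walking":
                phase = 2 * np.pi * config.gait_freq_hz * rel_t
                data[long_ax] = data[long_ax] + config.gait_amp_g * np.sin(phase)
                # smaller fore-aft component, out of phase with the vertical
                data[perp[0]] = data[perp[0]] + 0.5 * config.gait_amp_g * np.cos(phase)
        elif bout.posture == "lying":
            data[perp[0]] = np.ones(n)
        else:  # sitting: thigh horizontal, device rolled toward the other axis
            data[perp[1]] = np.ones(n)
        if config.noise_sd_g > 0:
            for a in axes:
                data[a] = data[a] + rng.normal(0.0, config.noise_sd_g, n)
        frame = pd.DataFrame({"timestamp": ts})
        for a in axes:
            frame[f"{a}_g"] = np.clip(data[a], -config.range_g, config.range_g)
        frames.append(frame)
    if not frames:
        return pd.DataFrame(columns=["timestamp", "x_g", "y_g", "z_g"])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values("timestamp", kind="stable", ignore_index=True)


def hospital_day_schedule(
    day_start: pd.Timestamp,
    active_min: float = 90.0,
    wear_h: float = 24.0,
    n_walk_bouts: int = 6,
    walk_fraction: float = 0.4,
    seed: int = 0,
) -> list[PostureBout]:
    """Build a realistic ward-day schedule with a target active time.

    Hospitalized arthroplasty patients spend well over 90% of the day
    lying or sitting; the schedule intersperses ``n_walk_bouts``
    standing+walking episodes through the worn part of the day so that
    standing plus walking totals ``active_min`` minutes.  Bout edges are
    aligned to whole seconds so the generating schedule doubles as an
    exact per-window oracle for the classifier.
    """
    rng = np.random.default_rng(seed)
    day_start = pd.Timestamp(day_start).floor("s")
    wear_s = int(round(wear_h * 3600))
    active_s = int(round(active_min * 60))
    if active_s > wear_s:
        raise ScheduleError("active time exceeds wear time")
    walk_s_total = int(round(active_s * walk_fraction))
    stand_s_total = active_s - walk_s_total
    bouts: list[PostureBout] = []
    # split the active seconds across episodes, each a stand+walk+stand sandwich
    n_ep = max(1, n_walk_bouts)
    walk_each = np.full(n_ep, walk_s_total // n_ep)
    walk_each[: walk_s_total % n_ep] += 1
    stand_each = np.full(n_ep, stand_s_total // n_ep)
    stand_each[: stand_s_total % n_ep] += 1
    rest_s = wear_s - active_s
    rest_each = np.full(n_ep + 1, rest_s // (n_ep + 1))
    rest_each[: rest_s % (n_ep + 1)] += 1
    cursor = day_start
    for i in range(n_ep):
        if rest_each[i] > 0:
            posture = "lying" if rng.random() < 0.6 else "sitting"
            bouts.append(PostureBout(cursor, float(rest_each[i]), posture))
            cursor += pd.Timedelta(seconds=int(rest_each[i]))
        half = int(stand_each[i]) // 2
        for dur, posture in (
            (half, "standing"),
            (int(walk_each[i]), "walking"),
            (int(stand_each[i]) - half, "standing"),
        ):
            if dur > 0:
                bouts.append(PostureBout(cursor, float(dur), posture))
                cursor += pd.Timedelta(seconds=dur)
    if rest_each[n_ep] > 0:
        bouts.append(PostureBout(cursor, float(rest_each[n_ep]), "lying"))
    return bouts


def scheduled_active_minutes(schedule: list[PostureBout]) -> float:
    """Standing plus walking minutes a schedule prescribes (the oracle)."""
    return sum(b.duration_s for b in schedule if b.posture in UPRIGHT) / 60.0


# ---------------------------------------------------------------------------
# cohort layer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupCovariates:
    """Marginal covariate distributions for one study arm.

    Age and BMI are log-normal (median/IQR-style skew); sex, surgery
    type and high comorbidity grade (ASA class 3) are Bernoulli.
    """

    age_median: float = 66.6
    age_log_sd: float = 0.118
    p_male: float = 0.63
    bmi_median: float = 27.7
    bmi_log_sd: float = 0.127
    p_tka: float = 0.77
    p_asa3: float = 0.17


@dataclass(frozen=True)
class CohortParams:
    """Generative model of the two-arm inpatient cohort.

    ``effect_min`` is the *true* (confounder-adjusted) group difference
    in first-postoperative-day active minutes.  ``confounder_strengths``
    maps covariates to their additive effect on the outcome; combined
    with between-arm covariate imbalance this induces the confounding
    the selection procedure must detect.  ``recovery_model`` holds the
    logistic coefficients of the dichotomous recovered-by-day-one
    endpoint.
    """

    n_control: int = 64
    n_intervention: int = 33
    effect_min: float = 28.4
    baseline_min: float = 70.9
    outcome_sd_min: float = 47.0
    control: GroupCovariates = field(default_factory=GroupCovariates)
    intervention: GroupCovariates = field(
        default_factory=lambda: GroupCovariates(
            age_median=61.5, p_male=0.45, p_tka=0.45, p_asa3=0.35
        )
    )
    confounder_strengths: dict = field(
        default_factory=lambda: {
            "age": -1.0,    # min per year, centred at the control median
            "sex": 0.0,
            "bmi": -1.0,    # min per kg/m^2, centred at the control median
            "surgery": 0.0,
            "asa_high": -5.0,
        }
    )
    recovery_model: dict = field(
        default_factory=lambda: {
            "intercept": 0.1,
            "group": 1.13,
            "asa_high": -0.9,
            "age": 0.0,
        }
    )
    los_median_days: int = 3
    n_missing_pod1: int = 0
    surgery_date: date = date(2019, 3, 4)
    seed: int = 0

    def __post_init__(self):
        if self.n_control < 0 or self.n_intervention < 0:
            raise ConfigError("group sizes must be >= 0")
        if self.outcome_sd_min < 0:
            raise ConfigError("outcome_sd_min must be >= 0")
        for g in (self.control, self.intervention):
            for p in (g.p_male, g.p_tka, g.p_asa3):
                if not 0 <= p <= 1:
                    raise ConfigError("probabilities must lie in [0, 1]")


def _draw_group(rng, cov: GroupCovariates, n: int, group: int, start_id: int):
    age = cov.age_median * np.exp(rng.normal(0, cov.age_log_sd, n))
    bmi = cov.bmi_median * np.exp(rng.normal(0, cov.bmi_log_sd, n))
    return pd.DataFrame(
        {
            "patient_id": [f"P{start_id + i:03d}" for i in range(n)],
            "group": group,
            "age": np.round(age, 1),
            "sex": (rng.random(n) < cov.p_male).astype(int),  # 1 = male
            "bmi": np.round(bmi, 1),
            "surgery": np.where(rng.random(n) < cov.p_tka, "TKA", "THA"),
            "asa_class": np.where(rng.random(n) < cov.p_asa3, 3, 2),
        }
    )


def simulate_outcomes(params: CohortParams = CohortParams()) -> pd.DataFrame:
    """Draw the covariate/outcome layer of a two-arm cohort.

    Returns one row per patient with covariates plus the two
    ground-truth outcomes: ``active_min_pod1`` following

        baseline + effect*group + sum_c beta_c * (c - c_ref) + noise

    (covariates centred at the control-arm reference, so the control
    mean converges to ``baseline_min``) and ``recovered_on_pod1`` drawn
    from the logistic ``recovery_model``.  This light layer is what
    Monte-Carlo parameter-recovery studies loop over;
    :func:`simulate_cohort` adds the daily summaries and
    assistance-scale logs that encode the same outcomes.
    """
    rng = np.random.default_rng(params.seed)
    ctrl = _draw_group(rng, params.control, params.n_control, 0, 1)
    intv = _draw_group(
        rng, params.intervention, params.n_intervention, 1, params.n_control + 1
    )
    patients = pd.concat([ctrl, intv], ignore_index=True)
    n = len(patients)
    patients["asa_high"] = (patients["asa_class"] == 3).astype(int)

    cs = params.confounder_strengths
    ref = params.control
    lin = (
        params.baseline_min
        + params.effect_min * patients["group"]
        + cs.get("age", 0.0) * (patients["age"] - ref.age_median)
        + cs.get("sex", 0.0) * (patients["sex"] - ref.p_male)
        + cs.get("bmi", 0.0) * (patients["bmi"] - ref.bmi_median)
        + cs.get("surgery", 0.0) * ((patients["surgery"] == "TKA").astype(int) - ref.p_tka)
        + cs.get("asa_high", 0.0) * (patients["asa_high"] - ref.p_asa3)
    )
    active = lin + rng.normal(0, params.outcome_sd_min, n)
    active = np.clip(active, 0, 1440)

    rm = params.recovery_model
    logit = (
        rm.get("intercept", 0.0)
        + rm.get("group", 0.0) * patients["group"]
        + rm.get("asa_high", 0.0) * patients["asa_high"]
        + rm.get("age", 0.0) * (patients["age"] - ref.age_median)
    )
    p_rec = 1.0 / (1.0 + np.exp(-logit))
    recovered = (rng.random(n) < p_rec).astype(int)

    los = params.los_median_days + rng.integers(-1, 2, n)
    los = np.maximum(los, 2)
    patients["los_days"] = los
    patients["walking_aid"] = rng.choice(
        ["two_crutches", "one_crutch", "walking_frame", "walker"],
        size=n,
        p=[0.85, 0.02, 0.06, 0.07],
    )
    patients["exclusion_reason"] = ""
    patients["active_min_pod1"] = np.round(active, 2)
    patients["recovered_on_pod1"] = recovered
    return patients


def simulate_cohort(
    params: CohortParams = CohortParams(),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw a full two-arm cohort: patients, daily summaries, mILAS logs.

    Returns ``(patients, daily, milas)``.  The outcome layer comes from
    :func:`simulate_outcomes`; this function turns it into study
    artifacts: per-day wear/activity summaries (day-one activity equals
    the drawn outcome) and a twice-daily assistance-scale log whose
    first zero total falls on or before the first postoperative day
    exactly when the drawn recovery flag is set.  The outcome columns
    are then dropped from the patient table — downstream analysis must
    recover them from the artifacts, as it would from real exports.
    """
    rng = np.random.default_rng(params.seed + 1)
    patients = simulate_outcomes(params)
    active = patients["active_min_pod1"].to_numpy()
    recovered = patients["recovered_on_pod1"].to_numpy()
    patients = patients.drop(columns=["active_min_pod1", "recovered_on_pod1"])

    # pick which patients lack a valid first-postoperative-day measurement
    missing_pod1 = set(
        rng.choice(patients["patient_id"], size=params.n_missing_pod1, replace=False)
        if params.n_missing_pod1
        else []
    )

    daily_rows = []
    milas_rows = []
    surgery = pd.Timestamp(params.surgery_date)
    for i, row in patients.iterrows():
        pid = row["patient_id"]
        pod1_invalid = pid in missing_pod1
        # surgery day: sensor fixed in the afternoon, partial coverage
        pod0_wear = float(np.round(rng.uniform(7.0, 11.0), 2))
        daily_rows.append(
            _daily_row(pid, surgery, 0, pod0_wear, rng.uniform(0, 10))
        )
        pod1_wear = float(np.round(rng.uniform(10.0, 18.0), 2)) if pod1_invalid else 24.0
        daily_rows.append(
            _daily_row(pid, surgery, 1, pod1_wear, float(active[i]))
        )
        # discharge day: partial coverage unless the stay is long; patients
        # whose day-one record is invalid keep a full day two so they still
        # contribute a valid measurement day
        pod2_wear = 24.0 if (row["los_days"] >= 4 or pod1_invalid) else float(
            np.round(rng.uniform(4.0, 10.0), 2)
        )
        daily_rows.append(
            _daily_row(pid, surgery, 2, pod2_wear, float(active[i]) * rng.uniform(0.8, 1.2))
        )
        milas_rows.extend(
            _milas_trajectory(rng, pid, surgery, int(recovered[i]), int(row["los_days"]))
        )

    daily = pd.DataFrame(daily_rows)
    milas = pd.DataFrame(milas_rows)
    return patients, daily, milas


def _daily_row(pid, surgery, pod, wear_h, active_min):
    active_min = float(np.clip(active_min, 0, wear_h * 60))
    return {
        "patient_id": pid,
        "calendar_date": (surgery + pd.Timedelta(days=pod)).date(),
        "pod_index": pod,
        "wear_h": wear_h,
        "valid": wear_h >= 20.0,
        "active_min": round(active_min, 2),
    }


_ITEMS = ("supine_to_sit", "sit_to_supine", "sit_to_stand", "walking", "stairs")


def _split_total(rng, total: int, needs_stairs: bool) -> dict:
    """Partition a 0-30 total over the five items, honouring the stairs rule."""
    items = {k: 0 for k in _ITEMS}
    usable = list(_ITEMS) if needs_stairs else [k for k in _ITEMS if k != "stairs"]
    cap = 6 * len(usable)
    total = min(total, cap)
    remaining = total
    for k in usable:
        items[k] = min(6, remaining)
        remaining -= items[k]
    # shuffle some weight around so items are not always saturated in order
    for _ in range(4):
        a, b = rng.choice(usable, 2, replace=False)
        move = int(rng.integers(0, 3))
        move = min(move, items[a], 6 - items[b])
        items[a] -= move
        items[b] += move
    return items


def _milas_trajectory(rng, pid, surgery, recovered_on_pod1, los_days):
    """Twice-daily assistance scores declining to zero at the right day."""
    needs_stairs = bool(rng.random() < 0.7)
    if recovered_on_pod1:
        zero_pod = 0 if rng.random() < 0.15 else 1
    else:
        zero_pod = int(rng.integers(2, 4)) if rng.random() < 0.7 else None
    start_total = int(rng.integers(12, 25))
    rows = []
    last_pod = max(2, los_days - 1)
    for pod in range(0, last_pod + 1):
        for sess, hour in enumerate((10, 16)):
            if zero_pod is not None and pod > zero_pod:
                total = 0
            elif zero_pod is not None and pod == zero_pod:
                # recovery reached at the afternoon session of that day
                total = 0 if sess == 1 else max(0, int(rng.integers(0, 4)))
            else:
                frac = 1.0 - pod / (zero_pod if zero_pod else last_pod + 2)
                total = max(1, int(round(start_total * max(frac, 0.1))))
            items = _split_total(rng, total, needs_stairs)
            rows.append(
                {
                    "patient_id": pid,
                    "timestamp": (surgery + pd.Timedelta(days=pod, hours=hour)),
                    **items,
                    "needs_stairs_at_home": needs_stairs,
                    "total": sum(items.values()),
                }
            )
    return rows


def inject_invalid_days(
    daily: pd.DataFrame,
    rule: str,
    seed: int = 0,
    n_patients: int = 1,
    patient_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Invalidate every measurement day of selected patients.

    Emulates the real-world exclusion mechanisms: ``delayed_fixation``
    (sensor attached too late on every day), ``malfunction`` (device
    stopped recording) and ``early_discharge`` (patient left before a
    full day accrued).  Targeted patients end with zero valid days; all
    other rows are untouched.
    """
    if rule not in EXCLUSION_RULES:
        raise ConfigError(
            f"unknown rule {rule!r}; expected one of {EXCLUSION_RULES}"
        )
    if daily.empty:
        raise InputError("no daily summaries to modify")
    out = daily.copy()
    if patient_ids is None:
        rng = np.random.default_rng(seed)
        pool = out["patient_id"].unique()
        patient_ids = list(rng.choice(pool, size=n_patients, replace=False))
    mask = out["patient_id"].isin(patient_ids)
    rng2 = np.random.default_rng(seed + 1)
    wear = {
        "delayed_fixation": lambda k: np.round(rng2.uniform(2.0, 12.0, k), 2),
        "malfunction": lambda k: np.round(rng2.uniform(0.0, 6.0, k), 2),
        "early_discharge": lambda k: np.round(rng2.uniform(6.0, 19.0, k), 2),
        "other": lambda k: np.round(rng2.uniform(0.0, 19.0, k), 2),
    }[rule](int(mask.sum()))
    out.loc[mask, "wear_h"] = wear
    out.loc[mask, "valid"] = False
    out.loc[mask, "active_min"] = np.minimum(
        out.loc[mask, "active_min"], out.loc[mask, "wear_h"] * 60
    )
    return out


def simulate_study_flow(
    params: CohortParams | None = None, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full enrolment-to-analysis fixture mirroring a pilot-study flow.

    Enrols the default 64 control + 33 intervention patients, then makes
    nine of them unanalyzable (five delayed sensor fixations, one
    discharge before any full day, three device malfunctions) and four
    further intervention patients miss the first postoperative day while
    keeping a later valid day.  The result: 88 analyzable patients of
    whom 84 contribute day-one activity data.
    """
    if params is None:
        params = CohortParams(seed=seed)
    else:
        params = replace(params, seed=seed)
    params = replace(params, n_missing_pod1=0)
    patients, daily, milas = simulate_cohort(params)
    rng = np.random.default_rng(seed + 7)
    ctrl_ids = patients.loc[patients["group"] == 0, "patient_id"].to_numpy()
    intv_ids = patients.loc[patients["group"] == 1, "patient_id"].to_numpy()
    ctrl_pick = list(rng.choice(ctrl_ids, size=3, replace=False))
    intv_pick = list(rng.choice(intv_ids, size=10, replace=False))
    assignments = {
        "delayed_fixation": ctrl_pick[:2] + intv_pick[:3],
        "early_discharge": [intv_pick[3]],
        "malfunction": [ctrl_pick[2]] + intv_pick[4:6],
    }
    for rule, ids in assignments.items():
        daily = inject_invalid_days(daily, rule, seed=seed, patient_ids=ids)
        patients.loc[patients["patient_id"].isin(ids), "exclusion_reason"] = rule
    # four intervention patients keep a valid later day but miss day one
    pod1_missing = intv_pick[6:10]
    m1 = daily["patient_id"].isin(pod1_missing) & (daily["pod_index"] == 1)
    daily.loc[m1, "wear_h"] = np.round(rng.uniform(10.0, 19.0, int(m1.sum())), 2)
    daily.loc[m1, "valid"] = False
    daily.loc[m1, "active_min"] = np.minimum(
        daily.loc[m1, "active_min"], daily.loc[m1, "wear_h"] * 60
    )
    m2 = daily["patient_id"].isin(pod1_missing) & (daily["pod_index"] == 2)
    daily.loc[m2, "wear_h"] = 24.0
    daily.loc[m2, "valid"] = True
    return patients, daily, milas


def exact_mean_groups(
    n0: int, n1: int, mean0: float, mean1: float, spread: float = 20.0
) -> pd.DataFrame:
    """Two-arm outcome table whose group means are *exactly* as given.

    Values are placed symmetrically about each mean (odd group sizes get
    one value at the mean), so the empirical means match to machine
    precision and a one-predictor least-squares fit returns the mean
    difference exactly.  Used for worked examples against published
    regression tables.
    """
    def sym(n, mean):
        half = n // 2
        offsets = spread * (np.arange(half) + 1) / half if half else np.array([])
        vals = np.concatenate([mean - offsets, mean + offsets])
        if n % 2:
            vals = np.append(vals, mean)
        return vals

    return pd.DataFrame(
        {
            "group": np.repeat([0, 1], [n0, n1]),
            "active_min_pod1": np.concatenate([sym(n0, mean0), sym(n1, mean1)]),
        }
    )
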