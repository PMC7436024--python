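# Methods

This note documents the models, conventions and numerical choices behind
`actiward`, and what the synthetic-data layer does and does not emulate.

## Sensor and signal model

The device model is a tri-axial accelerometer (±8 g range, 25 Hz) fixed
to the thigh. Orientation is encoded purely through gravity: when the
patient is upright the longitudinal (thigh) axis carries ≈ 1 g; when the
thigh is horizontal (lying, sitting) gravity falls on a perpendicular
axis and the longitudinal component is ≈ 0 g. Walking is simulated as a
sinusoid superimposed on the upright orientation — default amplitude
0.4 g at 1.5 Hz on the longitudinal axis with a half-amplitude
quadrature component fore-aft. These gait defaults are engineering
choices: they produce a signal that cleanly separates dynamic from
static windows while letting the noise parameter stress the thresholds;
they are not a biomechanical gait model (no double support, no walking
aids, no inter-stride variability). Sensor noise is i.i.d. Gaussian per
axis (default SD 0.03 g). Non-wear is represented as *absent samples* —
the device transmits nothing — so wear time and data coverage are the
same quantity by construction, which is exactly how delayed sensor
fixation produces invalid days.

## Classification pipeline

* **Noise reduction**: 4th-order Butterworth low-pass at 5 Hz, applied
  forward-backward (zero phase) per contiguous run of samples. 5 Hz
  preserves the gravity component and the gait band while removing
  sensor jitter; filtering never crosses a transmission gap (runs are
  split where the sampling interval exceeds 1.5× nominal), and runs too
  short to pad pass through unfiltered.
* **Windowing**: fixed non-overlapping one-second windows anchored at
  whole epoch seconds (a deterministic anchor is required for a "fixed"
  windowing). A window is classified only if it contains ≥ 20 of the 25
  expected samples; sparser seconds count as non-wear rather than being
  classified from fabricated data. Partial leading/trailing seconds are
  therefore discarded.
* **Activity statistic**: the largest per-axis mean absolute deviation
  about the window mean, threshold 0.1 g (configurable). A
  vector-magnitude dispersion was considered and rejected: a window
  whose longitudinal axis alternates ±1 g has constant magnitude and
  would register zero dispersion, yet is unambiguously movement. The
  per-axis statistic is sensitive to both gait oscillation and
  orientation change, and reduces to the same behaviour on magnitude-
  varying signals. The embedded statistic of the commercial device is
  unpublished; this one is a deliberate, documented stand-in with the
  same interface.
* **Orientation rule**: static windows are standing when the mean
  *absolute* longitudinal acceleration is ≥ 0.8 g, sedentary otherwise.
  The absolute value makes the rule insensitive to mounting polarity
  (which is not standardized); the boundary is inclusive so the rule is
  deterministic at exactly 0.8 g.
* **Aggregation**: per-minute counts of sedentary/standing/dynamic
  seconds; the three always partition the covered seconds.

On noiseless simulated signals with second-aligned bout edges, window
labels match the generating schedule exactly for all interior windows;
windows straddling bout boundaries are mixtures and carry no oracle.

## Daily summaries

Days are midnight-to-midnight local calendar days; the postoperative-day
(POD) index counts calendar days since surgery with the surgery day as
POD 0, so POD 1 is the first full postoperative day. Wear time is
covered (classified) time divided by 3600; a day is a valid measurement
day at ≥ 20 h (boundary inclusive). Active minutes = (standing +
dynamic seconds)/60. Analysis-day selection returns a value only for
valid days; missing is missing (complete-case analysis downstream, no
substitution).

## Assistance-scale scoring

Five items (supine-to-sit, sit-to-supine, sit-to-stand, walking,
stairs), each 0–6, total 0–30, 0 = full independence. The two transfer
directions are separate items, which is what makes five items total 30.
The stair item is forced to 0 when the patient has no stairs at home.
The percentage transform is the linear complement `(30 − total)/30 ×
100` (and `(6 − item)/6 × 100` per activity): the simplest monotone map
sending 0 → 100%. Recovery is a total of zero; with several assessments
per day the day's *minimum* governs, since recovery is a ratchet in
clinical use. The endpoint `recovered_on_pod1` is 1 exactly when the
first zero-total day is POD 1 or earlier.

## Regression and confounder selection

Linear models are OLS with t-based inference: 95% CI = B ±
t(0.975, n−p−1)·SE. The choice is checkable against printed tables: a
coefficient of 32.10 with SE 11.43 at 82 residual df implies the
interval 9.35–54.84. Logistic models are maximum likelihood
(Newton-Raphson, tolerance 1e-8) with Wald z intervals and OR = exp(B);
complete separation raises an error rather than returning estimates.
Designs are checked for rank before fitting and the collinear terms are
named in the error.

Change-in-estimate selection: from the crude (group-only) model, each
remaining candidate is added one at a time to the *current working
model*; percent change = |B_adj − B_ref|/|B_ref| × 100 on the group
coefficient, with B_ref the working model's coefficient (the procedure
is described as repeated on an evolving model; a crude-reference mode is
available via `reference="crude"`). The largest change ≥ 10% is
admitted; ties break by the fixed candidate order (age, sex, BMI,
surgery, ASA). The absolute relative difference is used because the
rule is stated without sign. Rows are restricted up front to complete
cases on outcome, group and all candidates so that coefficients are
compared on one fixed case set; per-model complete-case would make the
percent-change comparison incoherent when missingness differs between
candidates. The procedure is deterministic for a fixed cohort.

Descriptives use median/IQR for continuous variables (linear
interpolation between order statistics; conventions differ between
stats packages and this one is configurable in spirit — documented
here) and n (%) for categorical ones, with half-up percent rounding as
in printed clinical tables. The 0.05 significance level is used for
flagging only; no multiple-testing correction is applied, and none is
claimed.

## Synthetic cohort model

`simulate_outcomes` draws, per arm, covariates with log-normal age and
BMI (medians 66.6/61.5 years and 27.7 kg/m², log-SDs fitted to
IQR-scale skew) and Bernoulli sex, surgery type and high-ASA status.
Day-one active minutes follow

    active = baseline + effect·group + Σ_c β_c (c − c̄_control) + ε,
    ε ~ N(0, σ²),  clipped to [0, 1440]

with defaults baseline 70.9 min, true effect 28.4 min, σ = 47 min (the
residual scale that yields a group-coefficient SE near 11.4 at
n = 61/23). The recovery endpoint is Bernoulli with logit = 0.1 +
1.13·group − 0.9·asa_high. Clipping to the physical range [0, 1440]
introduces a floor effect at this noise scale (≈ 7% of control draws
hit zero), so fitted group effects sit somewhat below the nominal
parameter — the same attenuation a floor-censored outcome shows in real
activity data. At the default parameters the induced group difference
is ≈ 1 min smaller than the nominal one, which is well inside the
tolerances the sampling-distribution checks use; the large-n structural
numbers the acceptance script reports carry the full attenuation and
are labelled as model outputs, not nominal parameters.

The confounding structure is deliberate: the intervention arm is drawn
younger (median 61.5 vs 66.6 years) with an age slope of −1.0 min/year,
so age shifts the crude group coefficient by ≈ 12–13% — comfortably
over the 10% rule — while every other covariate shifts it by < 3%
(sex and surgery-type imbalances exist but carry no outcome effect);
likewise high ASA class is more prevalent in the intervention arm
(0.35 vs 0.15) with a −0.9 logit effect, making it the lone logistic
confounder. A marginal structure (a shift of ≈ 10.1%) was rejected
because "exactly one covariate crosses the threshold" should be a
property of the model, not of the sampling seed. At realistic study
sizes (n ≈ 97) the selection outcome still varies between seeds — as it
would between real pilot studies — which is why structure-level checks
run at large n.

`simulate_cohort` converts the drawn outcomes into study artifacts
(per-day summaries whose POD 1 row carries the drawn active minutes;
twice-daily assistance logs whose first zero lands on the drawn
recovery day) and removes the truth columns, so downstream analysis
must recover the outcomes from the artifacts. `simulate_study_flow`
adds the enrolment-flow features: 64 + 33 enrolled, five delayed
fixations, one pre-day-one discharge and three device malfunctions
leaving 88 analyzable, plus four intervention patients whose day-one
record is invalid while a later day is valid, leaving 84 with day-one
activity data.

What the generator does **not** emulate: real gait spectra and walking
aids, postural transitions (bout edges are instantaneous), sensor drift
and recalibration, informative missingness (invalid days are assigned,
not caused by low activity), correlated covariates beyond the
group-linked imbalances, and repeated-measures structure across days.
Passing tests therefore demonstrate the correctness of the chain's
logic and statistics under the stated model, not classifier validity on
real patients.

## Problem sizes and runtime choices

Structure-level checks of the generator and selection run at
n ≈ 5 000–9 000 patients, where Monte-Carlo error is negligible
relative to the 10% rule. Sampling-distribution checks use 500
replicate cohorts at the study scale (n = 84 linear, n = 500 logistic).
Signal-level end-to-end checks use a 4 h ward day (≈ 360 000 samples),
long enough to contain every posture and dozens of bout boundaries.
These sizes keep the full test suite under a minute while leaving all
conclusions limited by model structure, not by replication noise.

## Known limitations

* The dynamic-threshold default (0.1 g) is calibrated to the synthetic
  gait model, not to device data; on a real device it must be fitted
  against annotated postures.
* The logistic change-in-estimate rule conflates confounding with
  non-collapsibility: adding a strong outcome predictor moves the group
  log-odds coefficient even without confounding. The procedure
  implements the rule as specified; interpretation is the analyst's.
* No power/sample-size machinery is provided.
* Multi-level ASA or surgery coding beyond binary is rejected rather
  than expanded into dummies.
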