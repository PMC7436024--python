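"""Cohort statistics: descriptives, regressions, confounder selection.

The analytic chain of a quasi-experimental two-arm comparison:

* Table-1-style descriptives (median/IQR, counts/percent per arm);
* univariate and multiple **linear** regression of day-one active
  minutes on group membership (OLS, t-based inference);
* univariate and multiple **logistic** regression of the
  recovered-on-day-one endpoint (ML, Wald z inference, odds ratios);
* the iterative **change-in-estimate** confounder-selection rule:
  candidates whose addition shifts the main (group) coefficient by at
  least 10% enter the model, largest change first, until no candidate
  reaches the threshold.

Fits delegate to statsmodels; the selection procedure, which is the
analytical contribution here, is implemented directly and exposed both
as a function and as the scikit-learn-style
:class:`ChangeInEstimateSelector`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import (
    InputError,
    SelectionError,
    SeparationError,
    SingleClassError,
    SingularDesignError,
)

DEFAULT_CANDIDATES = ("age", "sex", "bmi", "surgery", "asa_high")

CONTINUOUS_FIELDS = ("age", "bmi", "los_days", "active_min_pod1")
CATEGORICAL_FIELDS = ("sex", "surgery", "asa_high", "walking_aid", "recovered_on_pod1")


@dataclass
class ModelFit:
    """A fitted regression in the published-table layout.

    ``table`` has one row per term with columns ``B, se, p, ci_low,
    ci_high`` (plus ``odds_ratio, or_ci_low, or_ci_high`` for logistic
    fits).  ``n_used`` counts the complete cases the fit consumed.
    """

    model_type: str
    table: pd.DataFrame
    n_used: int
    df_resid: float
    outcome: str

    def coef(self, term: str) -> float:
        return float(self.table.loc[term, "B"])


@dataclass
class SelectionStep:
    """One round of the change-in-estimate procedure."""

    reference_B: float
    evaluations: pd.DataFrame  # candidate, adjusted_B, pct_change
    chosen: str | None
    included: bool


@dataclass
class SelectionTrace:
    """Full audit trail of the iterative selection."""

    main: str
    threshold_pct: float
    crude_B: float
    steps: list[SelectionStep] = field(default_factory=list)

    @property
    def selected(self) -> list[str]:
        return [s.chosen for s in self.steps if s.included]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, step in enumerate(self.steps):
            for _, ev in step.evaluations.iterrows():
                rows.append(
                    {
                        "step": i + 1,
                        "reference_B": step.reference_B,
                        "candidate": ev["candidate"],
                        "adjusted_B": ev["adjusted_B"],
                        "pct_change": ev["pct_change"],
                        "chosen": ev["candidate"] == step.chosen and step.included,
                    }
                )
        return pd.DataFrame(rows)


def _iqr(x: pd.Series) -> float:
    q75, q25 = np.percentile(x.dropna(), [75, 25])  # linear interpolation
    return float(q75 - q25)


def describe(cohort: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Per-arm descriptive table: median (IQR) and n (%) rows.

    Continuous fields are summarised by median and interquartile range
    (hospital activity data are right-skewed), categorical fields by
    level counts and within-arm percentages.
    """
    if cohort.empty:
        raise InputError("empty cohort")
    rows = []
    groups = sorted(cohort[group_col].dropna().unique())
    for var in CONTINUOUS_FIELDS:
        if var not in cohort.columns:
            continue
        row = {"variable": var, "statistic": "median (IQR)"}
        for g in groups:
            vals = cohort.loc[cohort[group_col] == g, var].dropna()
            row[f"group_{g}"] = (
                f"{vals.median():.2f} ({_iqr(vals):.2f})" if len(vals) else ""
            )
        rows.append(row)
    for var in CATEGORICAL_FIELDS:
        if var not in cohort.columns:
            continue
        for level in sorted(cohort[var].dropna().unique()):
            row = {"variable": f"{var}={level}", "statistic": "n (%)"}
            for g in groups:
                sub = cohort.loc[cohort[group_col] == g, var].dropna()
                n = int((sub == level).sum())
                pct = 100.0 * n / len(sub) if len(sub) else 0.0
                # half-up rounding, the convention of printed clinical tables
                row[f"group_{g}"] = f"{n} ({int(np.floor(pct + 0.5))})"
            rows.append(row)
    return pd.DataFrame(rows)


def _design(cohort: pd.DataFrame, outcome: str, predictors: list[str]):
    cols = [outcome] + list(predictors)
    missing = [c for c in cols if c not in cohort.columns]
    if missing:
        raise InputError(f"cohort frame missing columns {missing}")
    data = cohort[cols].dropna()
    X = pd.DataFrame(index=data.index)
    for p in predictors:
        col = data[p]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.unique())
            if len(levels) > 2:
                raise InputError(f"predictor {p!r} has more than two levels")
            X[p] = (col == levels[-1]).astype(float)  # last level = exposed
        else:
            X[p] = col.astype(float)
    y = data[outcome].astype(float)
    Xc = sm.add_constant(X, has_constant="add")
    return y, Xc


def _check_rank(Xc: pd.DataFrame):
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        # name the offending terms: those whose removal restores full rank
        collinear = [
            c
            for c in Xc.columns
            if c != "const"
            and np.linalg.matrix_rank(Xc.drop(columns=c).to_numpy())
            == np.linalg.matrix_rank(Xc.to_numpy())
        ]
        raise SingularDesignError(
            f"design matrix is rank deficient; collinear terms: {collinear}",
            collinear_terms=collinear,
        )


def fit_linear(
    cohort: pd.DataFrame,
    outcome: str = "active_min_pod1",
    predictors: list[str] = ("group",),
) -> ModelFit:
    """Ordinary least squares with t-based standard inference.

    95% confidence intervals use ``B ± t(0.975, n-p-1)·SE`` and p-values
    the two-sided t distribution with residual degrees of freedom.
    Complete cases only; a rank-deficient design raises and names the
    collinear terms.
    """
    predictors = list(predictors)
    y, Xc = _design(cohort, outcome, predictors)
    if len(y) < len(predictors) + 2:
        raise InputError(
            f"need at least {len(predictors) + 2} complete cases, got {len(y)}"
        )
    _check_rank(Xc)
    res = sm.OLS(y, Xc).fit()
    ci = res.conf_int(alpha=0.05)
    table = pd.DataFrame(
        {
            "B": res.params,
            "se": res.bse,
            "p": res.pvalues,
            "ci_low": ci[0],
            "ci_high": ci[1],
        }
    )
    return ModelFit("linear", table, int(res.nobs), float(res.df_resid), outcome)


def fit_logistic(
    cohort: pd.DataFrame,
    outcome: str = "recovered_on_pod1",
    predictors: list[str] = ("group",),
) -> ModelFit:
    """Maximum-likelihood logistic regression with Wald inference.

    Newton-Raphson to a 1e-8 gradient tolerance; odds ratios are
    ``exp(B)`` with ``exp(B ± 1.96·SE)`` intervals.  Complete
    separation or other non-convergence raises without returning
    estimates, and a single-class outcome is rejected up front.
    """
    predictors = list(predictors)
    y, Xc = _design(cohort, outcome, predictors)
    if y.nunique() < 2:
        raise SingleClassError(f"outcome {outcome!r} has a single observed class")
    if len(y) < len(predictors) + 2:
        raise InputError(
            f"need at least {len(predictors) + 2} complete cases, got {len(y)}"
        )
    _check_rank(Xc)
    import warnings

    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            # separation is re-raised as an explicit error below
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xc).fit(disp=0, tol=1e-8, maxiter=200)
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as e:
        raise SeparationError(f"logistic fit failed: {e}") from e
    if not res.mle_retvals.get("converged", False):
        raise SeparationError("logistic fit did not converge (separation?)")
    if np.max(np.abs(res.params)) > 30:
        raise SeparationError("diverging coefficients indicate complete separation")
    z = stats.norm.ppf(0.975)
    table = pd.DataFrame(
        {
            "B": res.params,
            "se": res.bse,
            "p": res.pvalues,
            "ci_low": res.params - z * res.bse,
            "ci_high": res.params + z * res.bse,
        }
    )
    table["odds_ratio"] = np.exp(table["B"])
    table["or_ci_low"] = np.exp(table["ci_low"])
    table["or_ci_high"] = np.exp(table["ci_high"])
    return ModelFit("logistic", table, int(res.nobs), float(res.df_resid), outcome)


def wald_t_ci(b: float, se: float, df: int, alpha: float = 0.05) -> tuple[float, float]:
    """t-based confidence interval ``b ± t(1-alpha/2, df)·se``.

    The interval convention behind the linear-model tables; exposed so
    printed coefficients and standard errors can be turned back into
    the interval they imply.
    """
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return b - tcrit * se, b + tcrit * se


_FITTERS = {"linear": fit_linear, "logistic": fit_logistic}


def change_in_estimate_selection(
    cohort: pd.DataFrame,
    outcome: str,
    main: str = "group",
    candidates: tuple[str, ...] = DEFAULT_CANDIDATES,
    model_type: str = "linear",
    threshold_pct: float = 10.0,
    reference: str = "current",
) -> tuple[ModelFit, SelectionTrace]:
    """Iterative ≥10% change-in-estimate confounder selection.

    Starting from the crude (main-only) model, every remaining candidate
    is added one at a time to the current working model; the percent
    change in the main coefficient is ``|B_adj − B_ref| / |B_ref| ×
    100`` where ``B_ref`` is the working model's main coefficient
    (``reference='current'``, the default) or always the crude one
    (``reference='crude'``).  The candidate with the largest change at
    or above ``threshold_pct`` is admitted; the round repeats on the
    enlarged model until no candidate reaches the threshold.  Ties are
    broken by the fixed order of ``candidates``.

    Rows are restricted up front to complete cases on the outcome, the
    main determinant and every candidate, so coefficients are compared
    on one fixed case set throughout.
    """
    if model_type not in _FITTERS:
        raise InputError(f"model_type must be one of {sorted(_FITTERS)}")
    if main in candidates:
        raise SelectionError("main determinant cannot be its own candidate")
    if reference not in ("current", "crude"):
        raise SelectionError("reference must be 'current' or 'crude'")
    fitter = _FITTERS[model_type]
    cols = [outcome, main, *candidates]
    data = cohort.dropna(subset=[c for c in cols if c in cohort.columns])

    current = fitter(data, outcome=outcome, predictors=[main])
    crude_B = current.coef(main)
    if abs(crude_B) < 1e-10:  # numerically zero
        raise SelectionError(
            "crude main coefficient is zero; percent change undefined"
        )
    trace = SelectionTrace(main=main, threshold_pct=threshold_pct, crude_B=crude_B)
    included: list[str] = []
    remaining = list(candidates)
    while remaining:
        ref_B = crude_B if reference == "crude" else current.coef(main)
        evals = []
        for cand in remaining:
            fit = fitter(data, outcome=outcome, predictors=[main, *included, cand])
            adj_B = fit.coef(main)
            pct = abs(adj_B - ref_B) / abs(ref_B) * 100.0
            evals.append({"candidate": cand, "adjusted_B": adj_B, "pct_change": pct})
        evals_df = pd.DataFrame(evals)
        best_pct = evals_df["pct_change"].max()
        # ties fall to the earliest candidate in the fixed order
        best = evals_df.loc[evals_df["pct_change"] == best_pct, "candidate"].iloc[0]
        if best_pct >= threshold_pct:
            trace.steps.append(SelectionStep(ref_B, evals_df, best, True))
            included.append(best)
            remaining.remove(best)
            current = fitter(data, outcome=outcome, predictors=[main, *included])
        else:
            trace.steps.append(SelectionStep(ref_B, evals_df, None, False))
            break
    final = fitter(data, outcome=outcome, predictors=[main, *included])
    return final, trace


class ChangeInEstimateSelector(BaseEstimator):
    """Confounder selection as a scikit-learn-style estimator.

    ``fit`` takes the cohort frame and exposes the fitted attributes
    ``crude_B_``, ``selected_``, ``trace_``, ``model_`` and ``n_used_``.
    Parameters follow :func:`change_in_estimate_selection`.
    """

    def __init__(
        self,
        outcome: str = "active_min_pod1",
        main: str = "group",
        candidates: tuple[str, ...] = DEFAULT_CANDIDATES,
        model_type: str = "linear",
        threshold_pct: float = 10.0,
        reference: str = "current",
    ):
        self.outcome = outcome
        self.main = main
        self.candidates = candidates
        self.model_type = model_type
        self.threshold_pct = threshold_pct
        self.reference = reference

    def fit(self, X: pd.DataFrame, y=None):
        model, trace = change_in_estimate_selection(
            X,
            outcome=self.outcome,
            main=self.main,
            candidates=tuple(self.candidates),
            model_type=self.model_type,
            threshold_pct=self.threshold_pct,
            reference=self.reference,
        )
        self.model_ = model
        self.trace_ = trace
        self.crude_B_ = trace.crude_B
        self.selected_ = trace.selected
        self.n_used_ = model.n_used
        return self
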