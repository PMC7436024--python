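"""Regression machinery and change-in-estimate selection, with independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

import actiward as aw
from actiward.analysis import DEFAULT_CANDIDATES, change_in_estimate_selection
from actiward.errors import (
    InputError,
    SelectionError,
    SeparationError,
    SingleClassError,
    SingularDesignError,
)


def random_cohort(rng, n=60, p_group=0.4):
    """Small cohort with random covariate-outcome structure."""
    df = pd.DataFrame(
        {
            "group": (rng.random(n) < p_group).astype(int),
            "age": rng.normal(65, 8, n).round(1),
            "sex": rng.integers(0, 2, n),
            "bmi": rng.normal(27, 4, n).round(1),
            "surgery": rng.integers(0, 2, n),
            "asa_high": (rng.random(n) < 0.25).astype(int),
        }
    )
    betas = rng.normal(0, 3, 5)
    lin = (
        60
        + rng.normal(0, 25) * df["group"]
        + betas[0] * (df["age"] - 65)
        + betas[1] * df["sex"]
        + betas[2] * (df["bmi"] - 27)
        + betas[3] * df["surgery"]
        + betas[4] * df["asa_high"]
    )
    df["active_min_pod1"] = lin + rng.normal(0, 20, n)
    logit = 0.5 * df["group"] + 0.2 * betas[4] * df["asa_high"] - 0.03 * (df["age"] - 65)
    df["recovered_on_pod1"] = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    return df


# ---------------------------------------------------------------------------
# independent oracles (numpy / closed form only; no statsmodels)
# ---------------------------------------------------------------------------

def ols_normal_equations(df, outcome, predictors):
    X = np.column_stack([np.ones(len(df))] + [df[p].to_numpy(float) for p in predictors])
    y = df[outcome].to_numpy(float)
    return np.linalg.solve(X.T @ X, X.T @ y)


def logistic_loglik(df, outcome, predictors, beta):
    X = np.column_stack([np.ones(len(df))] + [df[p].to_numpy(float) for p in predictors])
    y = df[outcome].to_numpy(float)
    eta = X @ beta
    return float(np.sum(y * eta - np.log1p(np.exp(eta))))


def brute_force_cie(df, outcome, main, candidates, model_type, threshold=10.0):
    """Step-by-step re-execution of the iterative >=10% rule, from scratch."""
    def coef(predictors):
        if model_type == "linear":
            return ols_normal_equations(df, outcome, predictors)[1]
        # crude Newton iteration on the log-likelihood, independent code path
        X = np.column_stack(
            [np.ones(len(df))] + [df[p].to_numpy(float) for p in predictors]
        )
        y = df[outcome].to_numpy(float)
        beta = np.zeros(X.shape[1])
        for _ in range(60):
            mu = 1 / (1 + np.exp(-X @ beta))
            grad = X.T @ (y - mu)
            hess = X.T @ (X * (mu * (1 - mu))[:, None])
            beta = beta + np.linalg.solve(hess, grad)
        return beta[1]

    included, remaining = [], list(candidates)
    current = coef([main])
    while remaining:
        pcts = [
            (abs(coef([main, *included, c]) - current) / abs(current) * 100.0, c)
            for c in remaining
        ]
        best_pct = max(p for p, _ in pcts)
        best = next(c for p, c in pcts if p == best_pct)
        if best_pct < threshold:
            break
        included.append(best)
        remaining.remove(best)
        current = coef([main, *included])
    return included


class TestDescribe:
    def test_median_of_small_series(self):
        df = pd.DataFrame({"group": [0] * 5, "age": [1, 2, 3, 4, 5], "sex": 0})
        out = aw.describe(df)
        row = out[out["variable"] == "age"].iloc[0]
        assert row["group_0"].startswith("3.00")

    def test_categorical_percent(self):
        df = pd.DataFrame({"group": [0] * 64, "sex": [1] * 40 + [0] * 24})
        out = aw.describe(df)
        males = out[out["variable"] == "sex=1"].iloc[0]
        assert males["group_0"] == "40 (63)"

    def test_single_patient_iqr_zero(self):
        df = pd.DataFrame({"group": [0], "age": [70.0]})
        out = aw.describe(df)
        assert out[out["variable"] == "age"].iloc[0]["group_0"] == "70.00 (0.00)"

    def test_empty_cohort_rejected(self):
        with pytest.raises(InputError):
            aw.describe(pd.DataFrame(columns=["group", "age"]))


class TestFitLinear:
    def test_binary_predictor_recovers_group_means(self):
        df = aw.simulate.exact_mean_groups(61, 23, 70.89, 102.99)
        fit = aw.fit_linear(df, predictors=["group"])
        assert fit.coef("group") == pytest.approx(32.10, abs=1e-9)
        assert fit.coef("const") == pytest.approx(70.89, abs=1e-9)
        assert fit.n_used == 84

    def test_constant_outcome_gives_zero_slope(self):
        df = pd.DataFrame({"group": [0, 0, 1, 1, 0, 1], "active_min_pod1": 50.0})
        fit = aw.fit_linear(df, predictors=["group"])
        assert fit.coef("group") == pytest.approx(0.0, abs=1e-10)

    def test_exact_line_has_zero_residual_se(self):
        df = pd.DataFrame({"age": np.arange(1.0, 11.0)})
        df["active_min_pod1"] = 2.0 * df["age"]
        fit = aw.fit_linear(df, predictors=["age"])
        assert fit.coef("age") == pytest.approx(2.0, abs=1e-10)
        assert fit.table.loc["age", "se"] == pytest.approx(0.0, abs=1e-8)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            df = random_cohort(rng)
            preds = ["group", "age", "bmi"]
            fit = aw.fit_linear(df, predictors=preds)
            beta = ols_normal_equations(df, "active_min_pod1", preds)
            got = fit.table.loc[["const", *preds], "B"].to_numpy()
            assert np.allclose(got, beta, atol=1e-8)

    def test_t_interval_brackets_coefficient(self, small_cohort):
        fit = aw.fit_linear(small_cohort, predictors=["group", "age"])
        t = fit.table
        assert (t["ci_low"] <= t["B"]).all() and (t["B"] <= t["ci_high"]).all()

    def test_collinear_terms_named(self):
        df = pd.DataFrame(
            {"group": [0, 1, 0, 1, 1, 0], "age": [60, 61, 62, 63, 64, 65.0]}
        )
        df["age_copy"] = df["age"]
        df["active_min_pod1"] = 50.0 + df["age"]
        with pytest.raises(SingularDesignError) as err:
            aw.fit_linear(df, predictors=["group", "age", "age_copy"])
        assert {"age", "age_copy"} & set(err.value.collinear_terms)

    def test_too_few_cases_rejected(self):
        df = pd.DataFrame({"group": [0, 1], "active_min_pod1": [1.0, 2.0]})
        with pytest.raises(InputError):
            aw.fit_linear(df, predictors=["group"])


class TestWaldTCI:
    def test_published_scale_interval(self):
        # B=32.10, SE=11.43, 82 residual df -> the printed 9.35-54.84 interval
        lo, hi = aw.wald_t_ci(32.10, 11.43, 82)
        assert lo == pytest.approx(9.35, abs=0.02)
        assert hi == pytest.approx(54.84, abs=0.02)


class TestFitLogistic:
    def test_two_by_two_closed_form(self):
        # control 10/30 recovered, intervention 20/30: log-odds ratio = ln 4
        df = pd.DataFrame(
            {
                "group": [0] * 30 + [1] * 30,
                "recovered_on_pod1": [1] * 10 + [0] * 20 + [1] * 20 + [0] * 10,
            }
        )
        fit = aw.fit_logistic(df, predictors=["group"])
        assert fit.coef("group") == pytest.approx(np.log(4.0), abs=1e-6)
        assert fit.table.loc["group", "odds_ratio"] == pytest.approx(4.0, abs=1e-5)

    def test_independent_outcome_near_zero(self):
        df = pd.DataFrame(
            {
                "group": [0, 1] * 40,
                "recovered_on_pod1": ([0, 0, 1, 1] * 20),
            }
        )
        fit = aw.fit_logistic(df, predictors=["group"])
        assert abs(fit.coef("group")) < 1e-6

    def test_matches_likelihood_scan_on_small_fixture(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame({"group": rng.integers(0, 2, 20)})
        df["recovered_on_pod1"] = (
            rng.random(20) < 1 / (1 + np.exp(-(0.2 + 0.8 * df["group"])))
        ).astype(int)
        fit = aw.fit_logistic(df, predictors=["group"])
        b0, b1 = fit.coef("const"), fit.coef("group")
        # grid scan around the ML point: no grid point may beat it, and the
        # grid argmax must sit within one grid step (1e-3) of the estimate
        grid = np.arange(-3, 3, 1e-3)
        best = max(
            ((logistic_loglik(df, "recovered_on_pod1", ["group"], np.array([b0, g])), g)
             for g in grid)
        )
        assert best[1] == pytest.approx(b1, abs=1.5e-3)
        assert logistic_loglik(df, "recovered_on_pod1", ["group"], np.array([b0, b1])) >= best[0] - 1e-9

    def test_wald_or_interval(self):
        df = pd.DataFrame(
            {
                "group": [0] * 30 + [1] * 30,
                "recovered_on_pod1": [1] * 10 + [0] * 20 + [1] * 20 + [0] * 10,
            }
        )
        fit = aw.fit_logistic(df, predictors=["group"])
        row = fit.table.loc["group"]
        assert row["or_ci_low"] == pytest.approx(np.exp(row["B"] - 1.959964 * row["se"]), rel=1e-6)

    def test_complete_separation_raises(self):
        df = pd.DataFrame({"group": [0] * 10 + [1] * 10})
        df["recovered_on_pod1"] = df["group"]
        with pytest.raises(SeparationError):
            aw.fit_logistic(df, predictors=["group"])

    def test_single_class_outcome_rejected(self):
        df = pd.DataFrame({"group": [0, 1] * 5, "recovered_on_pod1": 1})
        with pytest.raises(SingleClassError):
            aw.fit_logistic(df, predictors=["group"])


class TestChangeInEstimate:
    def test_no_candidate_reaching_threshold_keeps_crude_model(self):
        rng = np.random.default_rng(3)
        n = 4000
        df = pd.DataFrame(
            {
                "group": rng.integers(0, 2, n),
                "age": rng.normal(65, 8, n),  # balanced: no confounding
                "sex": rng.integers(0, 2, n),
            }
        )
        df["active_min_pod1"] = 60 + 30 * df["group"] + rng.normal(0, 10, n)
        model, trace = change_in_estimate_selection(
            df, "active_min_pod1", candidates=("age", "sex")
        )
        assert trace.selected == []
        assert list(model.table.index) == ["const", "group"]
        assert not trace.steps[-1].included

    def test_constructed_cohort_selects_only_age(self):
        truth = aw.simulate_outcomes(
            aw.CohortParams(n_control=5000, n_intervention=2500, seed=17)
        )
        model, trace = change_in_estimate_selection(
            truth, "active_min_pod1", model_type="linear"
        )
        assert trace.selected == ["age"]
        assert list(model.table.index) == ["const", "group", "age"]

    def test_constructed_cohort_selects_only_asa(self):
        truth = aw.simulate_outcomes(
            aw.CohortParams(n_control=5000, n_intervention=2500, seed=17)
        )
        _, trace = change_in_estimate_selection(
            truth, "recovered_on_pod1", model_type="logistic"
        )
        assert trace.selected == ["asa_high"]

    def test_matches_brute_force_on_random_cohorts(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            df = random_cohort(rng)
            _, trace = change_in_estimate_selection(
                df, "active_min_pod1", candidates=DEFAULT_CANDIDATES
            )
            oracle = brute_force_cie(
                df, "active_min_pod1", "group", DEFAULT_CANDIDATES, "linear"
            )
            assert trace.selected == oracle

    def test_zero_crude_coefficient_aborts(self):
        df = pd.DataFrame(
            {
                "group": [0, 0, 1, 1] * 3,
                "age": list(range(12)),
                "active_min_pod1": [10.0, 20.0] * 6,
            }
        )
        with pytest.raises(SelectionError, match="zero"):
            change_in_estimate_selection(df, "active_min_pod1", candidates=("age",))

    def test_trace_is_deterministic(self, small_cohort):
        runs = [
            change_in_estimate_selection(small_cohort, "active_min_pod1")[1].to_frame()
            for _ in range(2)
        ]
        pd.testing.assert_frame_equal(runs[0], runs[1])

    def test_crude_reference_mode_differs_only_in_reference(self, small_cohort):
        _, trace = change_in_estimate_selection(
            small_cohort, "active_min_pod1", reference="crude"
        )
        for step in trace.steps:
            assert step.reference_B == pytest.approx(trace.crude_B)

    def test_selector_estimator_api(self, small_cohort):
        sel = aw.ChangeInEstimateSelector(threshold_pct=15.0)
        assert clone(sel).get_params()["threshold_pct"] == 15.0
        sel.fit(small_cohort)
        assert hasattr(sel, "model_") and hasattr(sel, "trace_")
        assert sel.crude_B_ == sel.trace_.crude_B

    def test_main_in_candidates_rejected(self, small_cohort):
        with pytest.raises(SelectionError):
            change_in_estimate_selection(
                small_cohort, "active_min_pod1", candidates=("group", "age")
            )
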