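"""Pairwise-complete correlations, change-on-change OLS, change-table assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actistep.cohort_stats import (
    build_change_table,
    change_regression,
    pearson_pairwise,
    standard_regressions,
)
from actistep.types import AnalysisSetMembership, PeriodSummary, ValidationError, VisitRecord


def table_of(trad, dig, t="six_mwd_m", d="daily_distance_m"):
    return pd.DataFrame({t: trad, d: dig})


def closed_form_r(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    sx, sy = x - x.mean(), y - y.mean()
    return float(np.sum(sx * sy) / np.sqrt(np.sum(sx**2) * np.sum(sy**2)))


class TestPearsonPairwise:
    def test_exact_linear_r_is_one(self):
        out = pearson_pairwise(table_of([1, 2, 3], [2, 4, 6]), ["six_mwd_m"], ["daily_distance_m"])
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_exact_antilinear_r_is_minus_one(self):
        out = pearson_pairwise(table_of([1, 2, 3], [3, 2, 1]), ["six_mwd_m"], ["daily_distance_m"])
        assert out["r"].iloc[0] == pytest.approx(-1.0)

    def test_missing_cell_drops_only_its_pair(self):
        t = table_of([1.0, 2.0, 3.0, 4.0], [2.0, np.nan, 5.0, 9.0])
        out = pearson_pairwise(t, ["six_mwd_m"], ["daily_distance_m"])
        assert out["n_pairs"].iloc[0] == 3
        assert out["r"].iloc[0] == pytest.approx(closed_form_r([1, 3, 4], [2, 5, 9]))

    def test_zero_variance_gives_absent_with_reason(self):
        out = pearson_pairwise(table_of([1, 1, 1], [2, 4, 6]), ["six_mwd_m"], ["daily_distance_m"])
        assert np.isnan(out["r"].iloc[0]) and out["note"].iloc[0] == "zero_variance"

    def test_low_n_flagged(self):
        out = pearson_pairwise(table_of([1, 2, 3], [2, 4, 7]), ["six_mwd_m"], ["daily_distance_m"])
        assert bool(out["low_n_flag"].iloc[0])

    def test_removing_row_absent_in_both_leaves_r_bit_identical(self):
        t1 = table_of([1.0, 2.0, 4.0, np.nan], [2.0, 3.0, 9.0, np.nan])
        t2 = t1.iloc[:3]
        r1 = pearson_pairwise(t1, ["six_mwd_m"], ["daily_distance_m"])["r"].iloc[0]
        r2 = pearson_pairwise(t2, ["six_mwd_m"], ["daily_distance_m"])["r"].iloc[0]
        assert r1 == r2

    @given(
        data=st.lists(
            st.tuples(st.floats(-100, 100), st.floats(-100, 100)), min_size=3, max_size=12
        ),
        a=st.floats(0.1, 10),
        b=st.floats(-50, 50),
    )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_affine_invariance(self, data, a, b):
        x = [p[0] for p in data]
        y = [p[1] for p in data]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        r0 = pearson_pairwise(table_of(x, y), ["six_mwd_m"], ["daily_distance_m"])["r"].iloc[0]
        x2 = [a * v + b for v in x]
        r1 = pearson_pairwise(table_of(x2, y), ["six_mwd_m"], ["daily_distance_m"])["r"].iloc[0]
        if np.isnan(r0):
            assert np.isnan(r1)
        else:
            assert r1 == pytest.approx(r0, rel=1e-9, abs=1e-9)

    def test_complete_case_mode_restricts_rows(self):
        t = pd.DataFrame(
            {
                "six_mwd_m": [1.0, 2.0, 3.0, 4.0],
                "borg": [1.0, np.nan, 2.0, 3.0],
                "daily_distance_m": [2.0, 4.0, 5.0, 9.0],
            }
        )
        out = pearson_pairwise(
            t, ["six_mwd_m", "borg"], ["daily_distance_m"], complete_cases=True
        )
        # row with missing borg dropped from every pair in complete-case mode
        assert (out["n_pairs"] == 3).all()
        out_pw = pearson_pairwise(t, ["six_mwd_m"], ["daily_distance_m"])
        assert out_pw["n_pairs"].iloc[0] == 4


class TestChangeRegression:
    def test_exact_line_recovered(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        t = table_of(2 * x, x)
        fit = change_regression(t, "six_mwd_m", ["daily_distance_m"])
        assert fit.coefficients["daily_distance_m"] == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_three_row_fit_matches_normal_equations(self):
        t = table_of([1.0, 4.0, 6.0], [2.0, 3.0, 7.0])
        fit = change_regression(t, "six_mwd_m", ["daily_distance_m"])
        X = np.column_stack([np.ones(3), [2.0, 3.0, 7.0]])
        beta = np.linalg.solve(X.T @ X, X.T @ np.array([1.0, 4.0, 6.0]))
        assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
        assert fit.coefficients["daily_distance_m"] == pytest.approx(beta[1], abs=1e-10)

    def test_residuals_orthogonal_to_predictors(self):
        rng = np.random.default_rng(11)
        t = pd.DataFrame(
            {
                "six_mwd_m": rng.normal(size=30),
                "daily_distance_m": rng.normal(size=30),
                "daily_standups": rng.normal(size=30),
            }
        )
        fit = change_regression(t, "six_mwd_m", ["daily_distance_m", "daily_standups"])
        X = t[["daily_distance_m", "daily_standups"]].to_numpy()
        yhat = fit.intercept + X @ np.array(
            [fit.coefficients["daily_distance_m"], fit.coefficients["daily_standups"]]
        )
        resid = t["six_mwd_m"].to_numpy() - yhat
        assert np.abs(X.T @ resid).max() < 1e-8

    def test_independent_noise_has_near_zero_r_squared(self):
        rng = np.random.default_rng(12)
        n = 10_000
        t = table_of(rng.normal(size=n), rng.normal(size=n))
        fit = change_regression(t, "six_mwd_m", ["daily_distance_m"])
        assert fit.r_squared < 0.05

    def test_rank_deficiency_names_collinear_predictor(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        t = pd.DataFrame(
            {"six_mwd_m": 2 * x, "daily_distance_m": x, "daily_steps": 3 * x}
        )
        with pytest.raises(ValidationError, match="daily_steps"):
            change_regression(t, "six_mwd_m", ["daily_distance_m", "daily_steps"])

    def test_too_few_rows_rejected(self):
        t = table_of([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValidationError, match="complete cases"):
            change_regression(t, "six_mwd_m", ["daily_distance_m"])


def summary(pid, measure, b, e):
    return PeriodSummary(pid, measure, b, 5, e, 5, change=e - b)


class TestBuildChangeTable:
    def _inputs(self):
        membership = {
            "P1": AnalysisSetMembership("P1", True, True),
            "P2": AnalysisSetMembership("P2", True, True),
            "P3": AnalysisSetMembership("P3", True, False, ["baseline_activity"]),
        }
        activity = {
            pid: {
                "distance_m": summary(pid, "distance_m", 5000.0, 5000.0 + delta),
                "steps": summary(pid, "steps", 7000.0, 7000.0 + delta),
                "standups": summary(pid, "standups", 24.0, 25.0),
                "resting_hr_bpm": summary(pid, "resting_hr_bpm", 76.0, 75.0),
            }
            for pid, delta in (("P1", 400.0), ("P2", -100.0), ("P3", 0.0))
        }
        visits = [
            VisitRecord("P1", "initial", six_mwd_m=339.0, borg=5.0),
            VisitRecord("P1", "final", six_mwd_m=366.0, borg=4.0),
            VisitRecord("P2", "initial", six_mwd_m=400.0),
            VisitRecord("P2", "final"),  # missing final 6MWD
        ]
        return activity, visits, {}, membership

    def test_visit_change_is_final_minus_initial(self):
        activity, visits, endpoints, membership = self._inputs()
        table = build_change_table(activity, visits, endpoints, membership)
        assert table.loc["P1", "six_mwd_m"] == pytest.approx(27.0)
        assert table.loc["P1", "borg"] == pytest.approx(-1.0)

    def test_absent_propagates(self):
        activity, visits, endpoints, membership = self._inputs()
        table = build_change_table(activity, visits, endpoints, membership)
        assert np.isnan(table.loc["P2", "six_mwd_m"])
        assert np.isnan(table.loc["P1", "digital_6mwd_m"])  # no walk endpoints given

    def test_excluded_patient_has_no_row(self):
        activity, visits, endpoints, membership = self._inputs()
        table = build_change_table(activity, visits, endpoints, membership)
        assert list(table.index) == ["P1", "P2"]
        assert table.loc["P1", "daily_distance_m"] == pytest.approx(400.0)


def test_standard_regressions_produce_single_and_joint_fits():
    rng = np.random.default_rng(13)
    n = 40
    x = rng.normal(size=(n, 3))
    t = pd.DataFrame(
        {
            "six_mwd_m": x @ [1.0, 0.5, 0.2] + rng.normal(scale=0.1, size=n),
            "daily_distance_m": x[:, 0],
            "daily_steps": x[:, 0] + rng.normal(scale=0.5, size=n),
            "daily_standups": x[:, 1],
            "digital_6mwd_m": x[:, 2],
        }
    )
    fits = standard_regressions(t)
    assert set(fits) == {"daily_distance_m", "daily_steps", "daily_standups", "digital_6mwd_m", "joint"}
    assert fits["joint"].r_squared > fits["daily_standups"].r_squared
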