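from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from imputebench import (AnalysisPlan, DescriptiveEstimand, MixedDataset,
                         RegressionEstimand, VariableSchema, complete_case,
                         fit_linear, fit_logistic, fractional_estimate,
                         pool_multiple)
from imputebench.core import FractionalAssignment, ImputationResult
from imputebench.estimation import estimate_all, estimate_multiple


class TestFits:
    def test_exact_line(self):
        x = np.array([[1.0], [2.0], [3.0]])
        beta = fit_linear(np.array([2.0, 4.0, 6.0]), x)
        np.testing.assert_allclose(beta, [0.0, 2.0], atol=1e-10)

    def test_balanced_table_odds_ratio_one(self):
        x = np.array([[0.0], [0.0], [1.0], [1.0]] * 10)
        y = np.array([0.0, 1.0, 0.0, 1.0] * 10)
        beta = fit_logistic(y, x)
        assert beta[1] == pytest.approx(0.0, abs=1e-8)

    def test_twelve_row_table_matches_independent_oracles(self):
        """OLS vs. explicit normal equations and IRLS vs. statsmodels Newton,
        both to 1e-6."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(21)
        X = rng.normal(size=(12, 2))
        y_lin = 1.0 + X @ [0.5, -1.2] + rng.normal(scale=0.3, size=12)
        beta = fit_linear(y_lin, X)
        X1 = np.column_stack([np.ones(12), X])
        oracle = np.linalg.solve(X1.T @ X1, X1.T @ y_lin)
        np.testing.assert_allclose(beta, oracle, atol=1e-6)

        y_log = (rng.random(12) < 1 / (1 + np.exp(-(X @ [1.0, -1.0])))).astype(float)
        if len(np.unique(y_log)) == 2:
            b = fit_logistic(y_log, X)
            o = sm.Logit(y_log, X1).fit(disp=0, tol=1e-10).params
            np.testing.assert_allclose(b, o, atol=1e-6)

    def test_weighted_equals_replicated_rows(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 1))
        y = (rng.random(8) < 0.5).astype(float)
        if len(np.unique(y)) < 2:
            y[0] = 1 - y[0]
        w = np.array([1, 2, 1, 3, 1, 2, 1, 1], dtype=float)
        bw = fit_logistic(y, X, weights=w)
        Xr = np.repeat(X, w.astype(int), axis=0)
        yr = np.repeat(y, w.astype(int))
        br = fit_logistic(yr, Xr)
        np.testing.assert_allclose(bw, br, atol=1e-8)


@pytest.fixture()
def toy():
    sch = (VariableSchema("x", "covariate", "continuous"),
           VariableSchema("b", "outcome", "binary", levels=("no", "yes"),
                          level_probs=(0.5, 0.5)),
           VariableSchema("y", "outcome", "continuous"))
    df = pd.DataFrame({
        "x": [0.1, 0.9, 0.4, 0.8, 0.2, 0.7, 0.3, 0.6, 0.5, 1.0],
        "b": ["no", "yes", "no", "yes", "no", "yes", "no", "yes", "no", "yes"],
        "y": [1.0, 2.0, np.nan, 4.0, 2.5, np.nan, 1.5, 3.5, np.nan, 4.5],
    })
    return MixedDataset(df, sch)


class TestCompleteCase:
    def test_hand_arithmetic_mean(self):
        sch = (VariableSchema("y", "outcome", "continuous"),)
        ds = MixedDataset(pd.DataFrame({"y": [1.0, 2.0, np.nan, 4.0]}), sch)
        plan = AnalysisPlan((DescriptiveEstimand("y"),))
        pe = complete_case(ds, plan)["mean(y)"]
        assert pe.value == pytest.approx(7 / 3, abs=1e-12)
        assert pe.n == 3

    def test_no_missing_equals_full_sample(self, toy):
        full = toy.copy()
        full.data["y"] = full.data["y"].fillna(1.0)
        plan = AnalysisPlan((
            DescriptiveEstimand("y"),
            RegressionEstimand("b", ("x", "y"), "logistic", "x"),
        ))
        cc = complete_case(full, plan)
        direct = estimate_all(full.data, full.schema, plan)
        for eid in plan.ids:
            assert cc[eid].value == pytest.approx(direct[eid], abs=1e-12)
            assert cc[eid].n == len(full)

    def test_regression_listwise_matches_fit_on_complete_rows(self, toy):
        """Logistic coefficient under listwise deletion equals the IRLS fit
        run on just the 7 complete rows."""
        plan = AnalysisPlan((RegressionEstimand("b", ("x", "y"), "logistic", "x"),))
        pe = complete_case(toy, plan)[plan.ids[0]]
        assert pe.n == 7
        sub = toy.data.dropna()
        y = (sub["b"] == "yes").to_numpy(dtype=float)
        X = sub[["x", "y"]].to_numpy(dtype=float)
        oracle = fit_logistic(y, X)
        assert pe.value == pytest.approx(oracle[1], abs=1e-10)

    def test_zero_surviving_rows_flagged_undefined(self):
        sch = (VariableSchema("y", "outcome", "continuous"),)
        ds = MixedDataset(pd.DataFrame({"y": [np.nan, np.nan]}), sch)
        pe = complete_case(ds, AnalysisPlan((DescriptiveEstimand("y"),)))["mean(y)"]
        assert np.isnan(pe.value) and pe.n == 0


class TestPooling:
    def test_mean_of_three(self):
        assert pool_multiple([1.0, 2.0, 3.0]) == 2.0

    def test_identical_datasets_pool_to_single_estimate(self, toy):
        full = toy.copy()
        full.data["y"] = full.data["y"].fillna(2.0)
        res = ImputationResult("multiple", "fcs", [full.copy(), full.copy()])
        plan = AnalysisPlan((DescriptiveEstimand("y"),))
        pooled = estimate_multiple(res, plan)["mean(y)"]
        assert pooled == pytest.approx(full.data["y"].mean(), abs=1e-12)

    def test_order_invariance_and_nan_propagation(self):
        assert pool_multiple([3.0, 1.0, 2.0]) == pool_multiple([1.0, 2.0, 3.0])
        assert np.isnan(pool_multiple([1.0, np.nan]))


class TestFractionalEstimate:
    def test_hand_arithmetic(self):
        """Donors {1,2,3}, one recipient with two half-weight donors valued 4
        and 6 (mean contribution 5): weighted mean (1+2+3+5)/4 = 2.75."""
        sch = (VariableSchema("y", "outcome", "continuous"),)
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0, np.nan, 4.0, 6.0]})
        # rows 4,5 are the donors of recipient 3; give them weight via fractions
        ds = MixedDataset(df.iloc[:4], sch)
        fa = FractionalAssignment({3: [0, 1]}, {3: [Fraction(1, 2), Fraction(1, 2)]})
        # recipient 3 borrows values 1.0 and 2.0 -> contribution 1.5
        res = ImputationResult("fractional", "fhd", [ds], fractional=fa)
        est = fractional_estimate(res, AnalysisPlan((DescriptiveEstimand("y"),)))
        assert est["mean(y)"] == pytest.approx((1 + 2 + 3 + 1.5) / 4, abs=1e-12)

    def test_zero_recipients_equals_unweighted(self, toy):
        full = toy.copy()
        full.data["y"] = full.data["y"].fillna(2.0)
        res = ImputationResult("fractional", "fhd", [full],
                               fractional=FractionalAssignment({}, {}))
        plan = AnalysisPlan((DescriptiveEstimand("y"),
                             RegressionEstimand("y", ("x",), "linear", "x")))
        est = fractional_estimate(res, plan)
        direct = estimate_all(full.data, full.schema, plan)
        for eid in plan.ids:
            assert est[eid] == pytest.approx(direct[eid], abs=1e-12)

    def test_weighted_logistic_matches_replication_oracle(self):
        """A fractional expansion with half weights fits the same logistic
        coefficient as physically replicating rows x1000 (tolerance 1e-3)."""
        rng = np.random.default_rng(8)
        n = 8
        x = rng.normal(size=n)
        b = np.array(["no", "yes"] * 4, dtype=object)
        sch = (VariableSchema("x", "covariate", "continuous"),
               VariableSchema("b", "outcome", "binary", levels=("no", "yes"),
                              level_probs=(0.5, 0.5)))
        df = pd.DataFrame({"x": x, "b": b})
        df.loc[6, "b"] = np.nan
        ds = MixedDataset(df, sch)
        fa = FractionalAssignment({6: [0, 1]}, {6: [Fraction(1, 2), Fraction(1, 2)]})
        res = ImputationResult("fractional", "fhd", [ds], fractional=fa)
        plan = AnalysisPlan((RegressionEstimand("b", ("x",), "logistic", "x"),))
        est = fractional_estimate(res, plan)[plan.ids[0]]
        # replication oracle: 1000 copies of full-weight rows, 500 of halves
        from imputebench.estimation import expand_fractional
        expanded, w = expand_fractional(ds, fa)
        reps = (w * 1000).astype(int)
        rep_df = expanded.loc[expanded.index.repeat(reps)]
        oracle = estimate_all(rep_df, ds.schema, plan)[plan.ids[0]]
        assert est == pytest.approx(oracle, abs=1e-3)


def test_all_estimators_agree_on_fully_observed_data(small_pop):
    plan = AnalysisPlan((
        DescriptiveEstimand("age_diagnosed"),
        RegressionEstimand("age_diagnosed", ("bmi", "age_group"), "linear", "bmi"),
    ))
    direct = estimate_all(small_pop.data, small_pop.schema, plan)
    cc = complete_case(small_pop, plan)
    mi = estimate_multiple(ImputationResult("multiple", "m", [small_pop.copy()]), plan)
    fr = fractional_estimate(
        ImputationResult("fractional", "f", [small_pop.copy()],
                         fractional=FractionalAssignment({}, {})), plan)
    for eid in plan.ids:
        assert cc[eid].value == pytest.approx(direct[eid], abs=1e-10)
        assert mi[eid] == pytest.approx(direct[eid], abs=1e-10)
        assert fr[eid] == pytest.approx(direct[eid], abs=1e-10)
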