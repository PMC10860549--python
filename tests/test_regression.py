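import numpy as np
import pandas as pd
import pytest

from bwdose.regression import (
    CohortTable,
    ScreeningThresholds,
    adjusted_r2,
    candidate_protocol,
    fit_ols,
    predictor_pools,
    r_squared,
    screen,
    select_best,
    stepwise_select,
)


def table_from(cols: dict, cohort="combined") -> CohortTable:
    return CohortTable(pd.DataFrame(cols), cohort=cohort)


class TestFitOLS:
    def test_exact_linear_fit(self):
        x = np.arange(10.0)
        t = table_from({"x": x, "y": 2 * x + 1})
        m = fit_ols(t, "y", ["x"])
        assert m.coefficients["x"] == pytest.approx(2.0)
        assert m.intercept == pytest.approx(1.0)
        assert m.r2 == pytest.approx(1.0)

    def test_constant_response_r2_zero(self):
        t = table_from({"x": np.arange(8.0), "y": np.full(8, 3.0)})
        m = fit_ols(t, "y", ["x"])
        assert m.coefficients["x"] == pytest.approx(0.0, abs=1e-12)
        assert m.r2 == 0.0

    def test_residuals_orthogonal_to_design(self, rng):
        n = 40
        df = {f"x{i}": rng.normal(size=n) for i in range(3)}
        df["y"] = df["x0"] + 0.5 * df["x1"] + rng.normal(size=n)
        m = fit_ols(table_from(df), "y", ["x0", "x1", "x2"])
        res = m._sm_result
        X = res.model.exog
        r = res.resid
        scale = np.abs(X.T @ res.model.endog).max()
        assert np.abs(X.T @ r).max() <= 1e-8 * max(scale, 1.0)

    def test_matches_normal_equations_oracle(self, rng):
        n, k = 10, 4
        X = rng.normal(size=(n, k))
        y = rng.normal(size=n)
        df = {f"x{i}": X[:, i] for i in range(k)}
        df["y"] = y
        m = fit_ols(table_from(df), "y", [f"x{i}" for i in range(k)])
        # high-precision explicit (X'X)^-1 X'y
        Xd = np.column_stack([np.ones(n), X]).astype(np.longdouble)
        yd = y.astype(np.longdouble)
        beta = np.linalg.solve((Xd.T @ Xd).astype(float), (Xd.T @ yd).astype(float))
        assert m.beta == pytest.approx(beta, rel=1e-8)
        xtx_inv = np.linalg.inv((Xd.T @ Xd).astype(float))
        assert np.allclose(m.xtx_inverse, xtx_inv, rtol=1e-8)

    def test_parameter_recovery_within_3se(self):
        rng = np.random.default_rng(42)
        n = 120
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        y = 3.0 + 1.5 * x1 - 0.8 * x2 + rng.normal(0, 0.7, n)
        m = fit_ols(table_from({"x1": x1, "x2": x2, "y": y}), "y", ["x1", "x2"])
        se = np.sqrt(m.s2 * np.diag(m.xtx_inverse))
        truth = [3.0, 1.5, -0.8]
        for b, t, s in zip(m.beta, truth, se):
            assert abs(b - t) < 3 * s

    def test_mean_consistency(self, rng):
        n = 30
        df = {"a": rng.normal(5, 2, n), "b": rng.uniform(0, 10, n)}
        df["y"] = 1 + df["a"] - 2 * df["b"] + rng.normal(size=n)
        t = table_from(df)
        m = fit_ols(t, "y", ["a", "b"])
        at_means = m.intercept + sum(
            m.coefficients[c] * t.data[c].mean() for c in ["a", "b"]
        )
        assert at_means == pytest.approx(t.data["y"].mean(), rel=1e-10)

    def test_rank_deficient_names_collinear_columns(self, rng):
        x = rng.normal(size=20)
        df = {"x1": x, "x2": 2 * x, "y": rng.normal(size=20)}
        with pytest.raises(np.linalg.LinAlgError, match="x1|x2"):
            fit_ols(table_from(df), "y", ["x1", "x2"])

    def test_too_few_rows_rejected(self, rng):
        df = {"x": [1.0, 2.0], "y": [1.0, 2.0]}
        with pytest.raises(ValueError):
            fit_ols(table_from(df), "y", ["x"])


class TestRSquared:
    @pytest.mark.parametrize(
        "r2, n, p, expected",
        [
            (0.909, 49, 3, 0.905),  # 2-predictor model on the rectal cohort
            (0.921, 94, 4, 0.918),  # 3-predictor model on the combined cohort
        ],
    )
    def test_printed_pairs_consistent(self, r2, n, p, expected):
        assert adjusted_r2(r2, n, p) == pytest.approx(expected, abs=5e-4)

    def test_perfect_fit_stays_one(self):
        assert adjusted_r2(1.0, 49, 3) == pytest.approx(1.0)

    def test_adjusted_never_exceeds_r2(self, rng):
        for _ in range(20):
            r2 = rng.uniform(0, 1)
            n = int(rng.integers(10, 100))
            p = int(rng.integers(1, 8))
            assert adjusted_r2(r2, n, p) <= r2 + 1e-12

    def test_r_squared_definition(self):
        y = [1.0, 2.0, 3.0, 4.0]
        assert r_squared(y, y) == 1.0
        assert r_squared(y, [2.5] * 4) == pytest.approx(0.0)
        assert r_squared([5.0, 5.0], [4.0, 6.0]) == 0.0  # zero-variance convention

    def test_n_le_p_rejected(self):
        with pytest.raises(ValueError):
            adjusted_r2(0.5, 3, 3)


class TestStepwise:
    def make_signal_table(self, seed=0, n=200):
        rng = np.random.default_rng(seed)
        x1, x2, x3 = (rng.normal(size=n) for _ in range(3))
        y = 2.0 * x1 + rng.normal(0, 1.0, n)
        return table_from({"x1": x1, "x2": x2, "x3": x3, "y": y})

    @pytest.mark.parametrize("method", ["stepwise", "forward", "backward"])
    def test_recovers_single_true_predictor(self, method):
        t = self.make_signal_table(seed=11)
        m = stepwise_select(t, "y", ["x1", "x2", "x3"], method)
        assert m.predictors == ["x1"]

    def test_null_model_empty_selection_rate(self):
        # single candidate: entry is a pure alpha = 0.05 type-I test,
        # so >= 95% of replicates should return the flagged intercept model
        empty = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            t = table_from({"x": rng.normal(size=50), "y": rng.normal(size=50)})
            m = stepwise_select(t, "y", ["x"], "forward")
            empty += m.provenance.get("empty_selection", False)
        assert empty >= 95

    def test_empty_selection_is_intercept_only(self, rng):
        t = table_from({"x": rng.normal(size=60), "y": rng.normal(size=60)})
        m = stepwise_select(t, "y", ["x"], "forward", alpha_enter=1e-9)
        assert m.predictors == []
        assert m.provenance["empty_selection"]
        assert m.intercept == pytest.approx(t.data["y"].mean())

    def test_backward_on_collinear_pool_raises(self, rng):
        x = rng.normal(size=30)
        t = table_from({"x1": x, "x2": 3 * x, "y": x + rng.normal(size=30)})
        with pytest.raises(np.linalg.LinAlgError):
            stepwise_select(t, "y", ["x1", "x2"], "backward")


class TestProtocol:
    def cohort(self, seed=3):
        from bwdose.phantom import CohortSpec, make_cohort

        table, truth = make_cohort(CohortSpec(n=49, calibration="rectal", seed=seed))
        return table, truth

    def test_pool_sizes(self):
        pools = predictor_pools()
        assert len(pools["full"]) == 17
        assert len(pools["wall-only"]) == 10
        assert len(pools["bladder-only"]) == 10

    def test_protocol_deterministic_and_nine_models(self):
        table, _ = self.cohort()
        a = candidate_protocol(table, "V30_cc")
        b = candidate_protocol(table, "V30_cc")
        assert len(a) == len(b) == 9
        for ma, mb in zip(a, b):
            assert ma.same_equation(mb)
            assert ma.provenance["method"] == mb.provenance["method"]

    def test_duplicates_flagged(self):
        table, _ = self.cohort()
        models = candidate_protocol(table, "V30_cc")
        dups = [m for m in models if m.provenance["duplicate_of"] is not None]
        for m in dups:
            assert m.same_equation(models[m.provenance["duplicate_of"]])

    def test_best_model_recovers_generative_pair(self):
        # V30 rule is Vbw + Pbw_1; the best model should contain the pair
        # (or a tightly collinear Pbw neighbor) on most seeds
        table, truth = self.cohort(seed=8)
        best = select_best(candidate_protocol(table, "V30_cc"))
        assert "Vbw_cc" in best.predictors
        assert any(p.startswith("Pbw") for p in best.predictors)


class TestScreen:
    def test_exact_fit_degenerate_pass(self):
        x = np.arange(12.0)
        t = table_from({"x": x, "y": 3 * x - 2})
        m = fit_ols(t, "x", ["y"])
        rep = screen(m)
        assert rep.passed and rep.degenerate
        assert rep.normality_pvalue is None

    def test_near_collinear_predictors_fail_vif(self):
        rng = np.random.default_rng(5)
        n = 60
        x1 = rng.normal(size=n)
        x2 = x1 + rng.normal(0, 0.02, n)  # corr ~ 0.999
        y = x1 + x2 + rng.normal(0, 0.5, n)
        m = fit_ols(table_from({"x1": x1, "x2": x2, "y": y}), "y", ["x1", "x2"])
        rep = screen(m)
        assert rep.max_vif > 5
        assert not rep.passed

    def test_vif_matches_definition(self, rng):
        n = 80
        x1 = rng.normal(size=n)
        x2 = 0.7 * x1 + rng.normal(0, 1, n)
        x3 = rng.normal(size=n)
        df = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3})
        df["y"] = x1 + rng.normal(size=n)
        m = fit_ols(CohortTable(df), "y", ["x1", "x2", "x3"])
        for j, col in enumerate(["x1", "x2", "x3"]):
            others = [c for c in ["x1", "x2", "x3"] if c != col]
            aux = fit_ols(CohortTable(df.rename(columns={col: "resp"})),
                          "resp", others)
            assert m.vif[col] == pytest.approx(1.0 / (1.0 - aux.r2), rel=1e-8)

    def test_heteroscedastic_data_fails_screen(self):
        rng = np.random.default_rng(77)
        n = 300
        x = rng.uniform(1, 10, n)
        y = 2 * x + rng.normal(0, 1, n) * x  # variance grows with x^2
        m = fit_ols(table_from({"x": x, "y": y}), "y", ["x"])
        rep = screen(m)
        assert rep.homoscedasticity_pvalue < 0.05
        assert not rep.passed

    def test_good_model_passes(self):
        rng = np.random.default_rng(10)
        n = 100
        x = rng.normal(size=n)
        y = 1 + 2 * x + rng.normal(0, 1, n)
        rep = screen(fit_ols(table_from({"x": x, "y": y}), "y", ["x"]))
        assert rep.passed and not rep.degenerate


class TestSelectBest:
    def passing(self, adj, preds, pool, idx=0):
        from bwdose.regression import FittedModel, ScreeningReport

        rep = ScreeningReport(0.001, {}, 1.0, 0.5, 0.5, True)
        return FittedModel(
            response="y", predictors=preds,
            coefficients={p: 1.0 for p in preds}, intercept=0.0,
            n=50, p=len(preds) + 1, residual_ss=1.0, s2=0.1,
            xtx_inverse=np.eye(len(preds) + 1), r2=adj, adjusted_r2=adj,
            vif={}, screening=rep, provenance={"pool": pool},
        )

    def test_highest_adjusted_r2_wins(self):
        a = self.passing(0.93, ["x"], "full")
        b = self.passing(0.91, ["x"], "wall-only")
        assert select_best([b, a]) is a

    def test_tie_breaks_fewer_predictors_then_pool(self):
        a = self.passing(0.9, ["x", "z"], "full")
        b = self.passing(0.9, ["x"], "bladder-only")
        c = self.passing(0.9, ["x"], "wall-only")
        assert select_best([a, b, c]) is c

    def test_failing_models_excluded(self):
        a = self.passing(0.99, ["x"], "full")
        a.screening.passed = False
        b = self.passing(0.5, ["x"], "full")
        assert select_best([a, b]) is b
        a.screening.passed = True

    def test_none_passing_raises(self):
        a = self.passing(0.9, ["x"], "full")
        a.screening.passed = False
        with pytest.raises(ValueError, match="no admissible"):
            select_best([a])
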