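"""Association statistics: screens, standardized OLS, selection, kappa."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.metrics import cohen_kappa_score

from dtialps.stats import (
    StandardizedOLS,
    StepwiseSelector,
    bonferroni_posthoc,
    cohens_kappa,
    fit_standardized_ols,
    residual_diagnostics,
    stepwise_select,
    univariate_screen,
    vif,
)


def frame_from(rng, n, p, names=None):
    X = rng.normal(size=(n, p))
    return pd.DataFrame(X, columns=names or [f"x{i}" for i in range(p)])


class TestStandardizedOLS:
    def test_single_predictor_beta_equals_pearson_r(self, rng):
        for _ in range(5):
            x = rng.normal(size=60)
            y = 0.5 * x + rng.normal(size=60)
            df = pd.DataFrame({"x": x})
            fit = fit_standardized_ols(df.assign(y=y), "y", ["x"])
            r, _ = sps.pearsonr(x, y)
            assert fit.coefficients["x"] == pytest.approx(r, abs=1e-12)

    def test_orthogonal_design_betas_are_marginal_correlations(self, rng):
        n = 200
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        # orthogonalize x2 against x1 in-sample
        x2 = x2 - np.polyfit(x1, x2, 1)[0] * x1
        x2 = (x2 - x2.mean()) / x2.std(ddof=1)
        y = x1 - 0.5 * x2 + rng.normal(size=n)
        df = pd.DataFrame({"a": x1, "b": x2, "y": y})
        fit = fit_standardized_ols(df, "y", ["a", "b"])
        ra = sps.pearsonr(x1, y)[0]
        rb = sps.pearsonr(x2, y)[0]
        assert fit.coefficients["a"] == pytest.approx(ra, abs=1e-10)
        assert fit.coefficients["b"] == pytest.approx(rb, abs=1e-10)
        assert fit.vif["a"] == pytest.approx(1.0, abs=1e-9)

    def test_duplicate_predictor_collinearity_error(self, rng):
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": x, "y": rng.normal(size=50)})
        with pytest.raises(ValueError, match="collinear"):
            fit_standardized_ols(df, "y", ["a", "b"])

    def test_matches_statsmodels_unstandardized_fit(self, rng):
        import statsmodels.api as sm

        n = 120
        df = frame_from(rng, n, 3, names=["a", "b", "c"])
        y = 2 + df["a"] - 0.3 * df["b"] + rng.normal(size=n)
        fit = fit_standardized_ols(df.assign(y=y), "y", ["a", "b", "c"])
        raw = sm.OLS(y, sm.add_constant(df)).fit()
        # standardized beta_j = raw beta_j * sd(x_j)/sd(y)
        for var in ("a", "b", "c"):
            expected = raw.params[var] * df[var].std(ddof=1) / y.std(ddof=1)
            assert fit.coefficients[var] == pytest.approx(expected, abs=1e-10)
            assert fit.p_values[var] == pytest.approx(raw.pvalues[var], abs=1e-10)
        assert fit.adjusted_r2 == pytest.approx(raw.rsquared_adj, abs=1e-10)

    def test_sklearn_estimator_contract(self, rng):
        df = frame_from(rng, 80, 2)
        y = df["x0"].to_numpy() + rng.normal(size=80)
        est = StandardizedOLS()
        assert est.get_params() == {"compute_vif": True}
        est.fit(df, y)
        assert est.coef_.shape == (2,)
        pred = est.predict(df)
        assert np.corrcoef(pred, y)[0, 1] > 0.5
        est.set_params(compute_vif=False)
        assert est.get_params()["compute_vif"] is False


class TestVif:
    def test_two_predictors_with_r_06_give_15625(self, rng):
        n = 400
        z = rng.normal(size=(n, 2))
        x1 = z[:, 0]
        x2 = 0.6 * z[:, 0] + np.sqrt(1 - 0.36) * z[:, 1]
        # force the sample correlation to exactly 0.6
        x1 = (x1 - x1.mean()) / x1.std(ddof=1)
        x2 = x2 - x2.mean()
        x2 = x2 - (x2 @ x1 / (x1 @ x1) - 0.6) * x1  # set sample corr
        x2 = x2 / x2.std(ddof=1)
        df = pd.DataFrame({"a": x1, "b": x2})
        r = np.corrcoef(x1, x2)[0, 1]
        got = vif(df, ["a", "b"])
        assert got["a"] == pytest.approx(1 / (1 - r**2), rel=1e-9)

    def test_near_duplicate_gives_huge_vif(self, rng):
        x = rng.normal(size=300)
        df = pd.DataFrame({"a": x, "b": x + rng.normal(0, 0.01, 300)})
        assert vif(df, ["a", "b"])["b"] > 10

    def test_orthogonal_predictors_unit_vif(self, rng):
        n = 100
        # QR against a leading constant column makes the remaining columns
        # mean-zero AND mutually orthogonal, so centering preserves exactness
        raw = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
        q, _ = np.linalg.qr(raw)
        df = pd.DataFrame(q[:, 1:], columns=["a", "b", "c"])
        for v in vif(df, ["a", "b", "c"]).values():
            assert v == pytest.approx(1.0, abs=1e-9)

    def test_perfect_collinearity_is_error(self, rng):
        x = rng.normal(size=50)
        with pytest.raises(ValueError, match="collinearity"):
            vif(pd.DataFrame({"a": x, "b": 2 * x}), ["a", "b"])


class TestUnivariateScreen:
    def test_outcome_equals_predictor_r_is_one(self, rng):
        x = rng.normal(size=30)
        df = pd.DataFrame({"age": x, "y": x})
        res = univariate_screen(df, "y", continuous=["age"], binary=[], anova=[])
        assert res[0].statistic == pytest.approx(1.0)
        assert res[0].p_value < 1e-20

    def test_identical_groups_t0_p1(self):
        df = pd.DataFrame({"sex": [0, 0, 0, 1, 1, 1], "y": [1.0, 2, 3, 1, 2, 3]})
        res = univariate_screen(df, "y", continuous=[], binary=["sex"], anova=[])
        assert res[0].statistic == pytest.approx(0.0, abs=1e-12)
        assert res[0].p_value == pytest.approx(1.0)

    def test_six_subject_fixture_matches_hand_covariance_ratio(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = np.array([2.0, 1, 4, 3, 6, 5])
        df = pd.DataFrame({"age": x, "y": y})
        res = univariate_screen(df, "y", continuous=["age"], binary=[], anova=[])
        # hand oracle: r = cov(x,y) / (sd x * sd y)
        cov = float(((x - x.mean()) * (y - y.mean())).sum() / 5)
        r_hand = cov / (x.std(ddof=1) * y.std(ddof=1))
        assert res[0].statistic == pytest.approx(r_hand, abs=1e-12)

    def test_single_level_binary_skipped(self, rng):
        df = pd.DataFrame({"diabetes": np.zeros(20, dtype=int), "y": rng.normal(size=20)})
        res = univariate_screen(df, "y", continuous=[], binary=["diabetes"], anova=[])
        assert res == []

    def test_constant_outcome_errors(self):
        df = pd.DataFrame({"age": [1.0, 2, 3], "y": [1.0, 1, 1]})
        with pytest.raises(ValueError, match="constant outcome"):
            univariate_screen(df, "y", continuous=["age"], binary=[], anova=[])

    def test_f_equals_t_squared_for_two_groups(self, rng):
        x = (rng.random(40) < 0.5).astype(int)
        y = rng.normal(size=40) + 0.5 * x
        t_res = univariate_screen(
            pd.DataFrame({"g": x, "y": y}), "y", continuous=[], binary=["g"], anova=[]
        )[0]
        f, p_f = sps.f_oneway(y[x == 0], y[x == 1])
        assert f == pytest.approx(t_res.statistic**2, rel=1e-10)
        assert p_f == pytest.approx(t_res.p_value, rel=1e-10)


class TestBonferroni:
    def test_three_groups_three_comparisons(self, rng):
        groups = [rng.normal(size=10) for _ in range(3)]
        out = bonferroni_posthoc(groups)
        assert len(out) == 3
        for (i, j), p in out.items():
            raw = sps.ttest_ind(groups[i], groups[j]).pvalue
            assert p == pytest.approx(min(1.0, raw * 3))
            assert p >= raw  # corrected never below raw

    def test_identical_groups_all_p_one(self):
        g = np.array([1.0, 2, 3, 4])
        out = bonferroni_posthoc([g, g.copy(), g.copy()])
        assert all(p == 1.0 for p in out.values())

    def test_planted_shift_detected_only_for_its_pairs(self, rng):
        base = [rng.normal(size=40) for _ in range(2)]
        shifted = rng.normal(size=40) + 3.0
        out = bonferroni_posthoc(base + [shifted])
        assert out[(0, 1)] > 0.05
        assert out[(0, 2)] < 0.05 and out[(1, 2)] < 0.05

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            bonferroni_posthoc([np.array([1.0, 2.0]), np.array([])])


class TestStepwise:
    def test_alpha_enter_one_returns_full_model(self, rng):
        df = frame_from(rng, 100, 4)
        y = rng.normal(size=100)
        fit = stepwise_select(
            df.assign(y=y), "y", candidates=list(df.columns),
            alpha_enter=1.0, alpha_remove=1.0,
        )
        assert set(fit.forward_set) == set(df.columns)

    def test_alpha_enter_zero_returns_empty_model(self, rng):
        df = frame_from(rng, 100, 4)
        y = df["x0"].to_numpy() * 2 + rng.normal(size=100)
        fit = stepwise_select(
            df.assign(y=y), "y", candidates=list(df.columns),
            alpha_enter=0.0, alpha_remove=0.0,
        )
        assert fit.variables == []
        assert fit.forward_set == []

    def test_strong_predictor_among_nulls_selected(self, rng):
        """The strong predictor always enters first; the exact singleton set
        appears at roughly the no-false-entry rate (1 - alpha)^5 ~ 0.77."""
        exact = 0
        for rep in range(40):
            local = np.random.default_rng(1000 + rep)
            df = frame_from(local, 500, 6)
            y = 0.5 * df["x2"].to_numpy() + local.normal(size=500)
            fit = stepwise_select(df.assign(y=y), "y", candidates=list(df.columns))
            assert fit.forward_set[0] == "x2"
            exact += fit.forward_set == ["x2"]
        assert exact >= 27  # ~3 SD below the expected 0.77 * 40

    def test_null_inclusion_rate_close_to_alpha(self):
        """Under the global null, each candidate enters at ~alpha_enter."""
        included = 0
        total = 0
        k = 6
        for rep in range(300):
            local = np.random.default_rng(5000 + rep)
            df = frame_from(local, 120, k)
            y = local.normal(size=120)
            fit = stepwise_select(df.assign(y=y), "y", candidates=list(df.columns))
            included += len(fit.forward_set)
            total += k
        rate = included / total
        # sequential entry inflates the per-variable rate slightly above the
        # nominal level; allow for that plus Monte-Carlo error
        assert abs(rate - 0.05) < 0.03

    def test_forward_backward_disagreement_flagged_and_forward_reported(self, rng):
        df = frame_from(rng, 200, 3)
        y = 0.6 * df["x0"].to_numpy() + rng.normal(size=200)
        sel = StepwiseSelector(alpha_enter=0.05, alpha_remove=0.10).fit(df, y)
        assert sel.selected_ == sel.forward_set_
        assert sel.directions_disagree_ == (set(sel.forward_set_) != set(sel.backward_set_))

    def test_selector_transform_and_support(self, rng):
        df = frame_from(rng, 300, 4)
        y = df["x1"].to_numpy() + 0.1 * rng.normal(size=300)
        sel = StepwiseSelector().fit(df, y)
        assert "x1" in sel.selected_
        assert sel.get_support().sum() == len(sel.selected_)
        assert list(sel.transform(df).columns) == sel.selected_

    def test_alpha_order_validated(self, rng):
        df = frame_from(rng, 50, 2)
        with pytest.raises(ValueError, match="alpha_enter"):
            StepwiseSelector(alpha_enter=0.2, alpha_remove=0.1).fit(df, rng.normal(size=50))


class TestCohensKappa:
    def test_identical_ratings_kappa_one(self):
        a = [0, 1, 2, 1, 0, 2]
        assert cohens_kappa(a, list(a)) == 1.0

    def test_one_rater_constant_kappa_zero(self, rng):
        a = rng.integers(0, 3, 50)
        b = np.ones(50, dtype=int)
        assert cohens_kappa(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_2x2(self):
        # 40 agree on 0, 40 agree on 1, 10+10 disagree: p_o=0.8, p_e=0.5
        a = [0] * 50 + [1] * 50
        b = [0] * 40 + [1] * 10 + [0] * 10 + [1] * 40
        assert cohens_kappa(a, b) == pytest.approx((0.8 - 0.5) / 0.5)

    def test_matches_sklearn_on_random_ratings(self, rng):
        for _ in range(10):
            a = rng.integers(0, 3, 80)
            b = np.where(rng.random(80) < 0.7, a, rng.integers(0, 3, 80))
            assert cohens_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)

    def test_degenerate_perfect_agreement_defined_as_one(self):
        assert cohens_kappa([2, 2, 2], [2, 2, 2]) == 1.0

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            cohens_kappa([1, 2], [1, 2, 3])


class TestResidualDiagnostics:
    def test_gaussian_residuals_pass_at_nominal_rate(self):
        passes = 0
        n_rep = 200
        for rep in range(n_rep):
            local = np.random.default_rng(rep)
            df = pd.DataFrame({"x": local.normal(size=80)})
            y = df["x"].to_numpy() + local.normal(size=80)
            fit = fit_standardized_ols(df.assign(y=y), "y", ["x"])
            passes += residual_diagnostics(fit).normality_pass
        assert passes / n_rep == pytest.approx(0.95, abs=0.05)

    def test_heavy_tailed_residuals_fail_often(self):
        fails = 0
        n_rep = 60
        for rep in range(n_rep):
            local = np.random.default_rng(rep)
            df = pd.DataFrame({"x": local.normal(size=80)})
            y = df["x"].to_numpy() + local.standard_t(df=1, size=80)
            fit = fit_standardized_ols(df.assign(y=y), "y", ["x"])
            fails += not residual_diagnostics(fit).normality_pass
        assert fails / n_rep > 0.5

    def test_saturated_model_skipped_with_note(self, rng):
        df = pd.DataFrame({"a": [1.0, 2, 3, 0.5], "b": [0.0, 1, 0.2, 1.1]})
        y = np.array([1.0, 2.0, 1.5, 0.0])
        fit = fit_standardized_ols(df.assign(y=y), "y", ["a", "b"])
        diag = residual_diagnostics(fit)
        assert diag.skipped
        assert "saturated" in diag.note
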