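"""Penalized model selection, final logistic models and fit diagnostics."""

import numpy as np
import pandas as pd
import pytest

from oracles import newton_logistic
from rxadherence.models import (
    PenalizedFit,
    compare_penalties,
    cramers_v,
    cv_penalized_fit,
    evaluate_binary,
    final_logistic_from_lasso,
    hosmer_lemeshow,
    make_design,
    nagelkerke_r2,
    plain_logistic_report,
    variables_surviving_lasso,
    vif_screen,
)


def planted_logistic_data(seed, n=2000, n_true=3, n_null=6, beta=0.7):
    """Binary covariates with three true effects (+, -, +) and nulls."""
    rng = np.random.default_rng(seed)
    X = rng.random((n, n_true + n_null)) < 0.5
    signs = np.array([1.0, -1.0, 1.0])
    lp = -0.3 + (X[:, :n_true] * (beta * signs)).sum(axis=1)
    y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float)
    df = pd.DataFrame(
        {f"x{j}": pd.Categorical(X[:, j].astype(int)) for j in range(n_true + n_null)}
    )
    return df, y, signs


class TestDesign:
    def test_reference_is_most_frequent(self):
        df = pd.DataFrame({"band": ["m", "m", "m", "y", "o"]})
        d = make_design(df)
        assert d.reference["band"] == "m"
        assert set(d.columns) == {"band_y", "band_o"}

    def test_l_minus_one_columns(self):
        df = pd.DataFrame({"a": ["p", "q", "r", "p"], "b": [0, 1, 0, 1]})
        d = make_design(df)
        assert len(d.columns_of("a")) == 2
        assert len(d.columns_of("b")) == 1


class TestCramersV:
    def test_perfect_association(self):
        a = ["x"] * 10 + ["y"] * 10
        b = ["u"] * 10 + ["v"] * 10
        assert cramers_v(a, b) == pytest.approx(1.0)

    def test_independence(self):
        a = (["x"] * 25 + ["y"] * 25) * 2
        b = ["u"] * 50 + ["v"] * 50
        assert cramers_v(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_table(self):
        # [[20, 10], [10, 20]]: chi2 = 20/3, V = sqrt(chi2/60) = 1/3
        a = ["x"] * 30 + ["y"] * 30
        b = ["u"] * 20 + ["v"] * 10 + ["u"] * 10 + ["v"] * 20
        assert cramers_v(a, b) == pytest.approx(1 / 3, abs=1e-9)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            cramers_v(["x"] * 10, ["u"] * 5 + ["v"] * 5)


class TestVif:
    def test_orthogonal_columns(self):
        X = np.kron(np.eye(3), np.ones((4, 1)))[:, :2]  # disjoint indicators
        d = make_design(pd.DataFrame({"a": X[:, 0], "b": X[:, 1]}))
        out = vif_screen(d)
        assert (out["vif"] < 1.6).all()
        assert not out["flag"].any()

    def test_duplicated_column_infinite(self):
        x = np.array([0, 1, 0, 1, 1, 0], float)
        df = pd.DataFrame({"a": x, "b": x})
        d = make_design(df)
        out = vif_screen(d)
        assert np.isinf(out["vif"]).all()
        assert out["flag"].all()

    def test_known_correlation_closed_form(self):
        # two standardized columns with exact sample correlation 0.9
        n = 40
        u = np.tile([1.0, -1.0], n // 2)
        v = np.repeat([1.0, -1.0], n // 2)
        x2 = 0.9 * u + np.sqrt(1 - 0.81) * v
        X = np.column_stack([u, x2])
        d = make_design(pd.DataFrame({"a": ["l"] * n}))  # placeholder
        d.X, d.columns, d.var_of = X, ["c1", "c2"], {"c1": "a", "c2": "b"}
        out = vif_screen(d)
        assert out["vif"].iloc[0] == pytest.approx(1 / (1 - 0.81), rel=1e-6)


class TestPenalizedFit:
    def test_huge_lambda_gives_null_model(self):
        df, y, _ = planted_logistic_data(0, n=800)
        d = make_design(df)
        fit = cv_penalized_fit(d, y, "lasso", seed=1, lambda_grid=np.array([1e6]))
        assert np.abs(fit.coefficients).max() == 0.0
        prev = y[fit.train_idx].mean()
        assert fit.intercept == pytest.approx(np.log(prev / (1 - prev)), abs=1e-6)

    def test_zero_lambda_matches_newton_oracle(self):
        df, y, _ = planted_logistic_data(1, n=600, n_null=2)
        d = make_design(df)
        fit = cv_penalized_fit(d, y, "lasso", seed=2, lambda_grid=np.array([1e-10]))
        beta = newton_logistic(d.X[fit.train_idx], y[fit.train_idx])
        assert fit.intercept == pytest.approx(beta[0], abs=1e-4)
        assert np.allclose(fit.coefficients.to_numpy(), beta[1:], atol=1e-4)

    def test_ridge_keeps_all_nonzero_lasso_zeroes(self):
        df, y, _ = planted_logistic_data(3, n=1200)
        d = make_design(df)
        ridge = cv_penalized_fit(d, y, "ridge", seed=3)
        lasso = cv_penalized_fit(d, y, "lasso", seed=3)
        assert (np.abs(ridge.coefficients) > 0).all()
        assert (np.abs(lasso.coefficients) < 1e-10).any()

    def test_single_class_outcome_rejected(self):
        df, y, _ = planted_logistic_data(4, n=200)
        d = make_design(df)
        with pytest.raises(ValueError):
            cv_penalized_fit(d, np.ones_like(y), "lasso", seed=0)

    def test_nonzero_count_monotone_along_path(self):
        """On the CV grid the mean number of active coefficients shrinks as
        lambda grows (checked pairwise on the descending grid)."""
        df, y, _ = planted_logistic_data(5, n=1500)
        d = make_design(df)
        fit = cv_penalized_fit(d, y, "lasso", seed=5)
        nnz = fit.cv_table["mean_nonzero"].to_numpy()  # lambda descending
        assert (np.diff(nnz) >= -1e-9).all() or (np.diff(nnz[::-1]) <= 1e-9).all()

    def test_selection_recovers_planted_variables(self):
        hits = 0
        for seed in range(5):
            df, y, signs = planted_logistic_data(seed, n=3000)
            d = make_design(df)
            fit = cv_penalized_fit(d, y, "lasso", seed=seed)
            kept = variables_surviving_lasso(fit, d)
            true_in = all(f"x{j}" in kept for j in range(3))
            nulls = sum(f"x{j}" in kept for j in range(3, 9))
            hits += true_in and nulls <= 1
        assert hits >= 4


class TestComparePenalties:
    @staticmethod
    def _fit(penalty, rmse, r2, auc):
        return PenalizedFit(
            penalty=penalty, lambda_grid=np.array([1.0]), chosen_lambda=1.0,
            coefficients=pd.Series(dtype=float), intercept=0.0,
            train_idx=np.array([0]), test_idx=np.array([1]),
            metrics={"rmse": rmse, "r_squared": r2, "auc": auc},
            cv_table=pd.DataFrame(), seed=0,
        )

    def test_concordant_winner(self):
        fits = [self._fit("ridge", 0.42, 0.01, 0.6),
                self._fit("lasso", 0.40, 0.05, 0.7),
                self._fit("elastic_net", 0.41, 0.03, 0.65)]
        out = compare_penalties(fits)
        assert out.loc[out["winner"], "penalty"].tolist() == ["lasso"]
        assert not out["discordant"].any()

    def test_discordant_no_winner(self):
        fits = [self._fit("ridge", 0.40, 0.01, 0.6),
                self._fit("lasso", 0.42, 0.05, 0.7),
                self._fit("elastic_net", 0.41, 0.03, 0.65)]
        out = compare_penalties(fits)
        assert not out["winner"].any()
        assert out["discordant"].all()

    def test_exact_tie_broken_by_auc(self):
        fits = [self._fit("ridge", 0.40, 0.05, 0.60),
                self._fit("lasso", 0.40, 0.05, 0.70)]
        out = compare_penalties(fits)
        assert out.loc[out["winner"], "penalty"].tolist() == ["lasso"]


class TestFinalModel:
    def test_group_survival_rule(self):
        df, y, _ = planted_logistic_data(0, n=400)
        d = make_design(df)
        fit = cv_penalized_fit(d, y, "lasso", seed=0, lambda_grid=np.array([1e6]))
        # zero everything, then switch on one dummy of x1 only
        fit.coefficients_1se[:] = 0.0
        fit.coefficients_1se[d.columns_of("x1")[0]] = 0.5
        assert variables_surviving_lasso(fit, d) == ["x1"]
        fit.coefficients[:] = 0.0
        assert variables_surviving_lasso(fit, d, rule="primary") == []

    def test_signs_match_planted_effects(self):
        df, y, signs = planted_logistic_data(6, n=3000)
        d = make_design(df)
        fit = cv_penalized_fit(d, y, "lasso", seed=6)
        rep = final_logistic_from_lasso(fit, d, y)
        tbl = rep.coefficients.set_index("term")
        for j, s in enumerate(signs):
            term = f"x{j}_1"
            if term in tbl.index:
                assert np.sign(tbl.loc[term, "coef"]) == s

    def test_intercept_only_when_nothing_survives(self):
        df, y, _ = planted_logistic_data(7, n=300, beta=0.0)
        d = make_design(df)
        fit = cv_penalized_fit(d, y, "lasso", seed=7, lambda_grid=np.array([1e6]))
        with pytest.warns(UserWarning):
            rep = final_logistic_from_lasso(fit, d, y)
        assert rep.selected_variables == []
        assert len(rep.coefficients) == 1

    def test_sensitivity_mode_same_signs(self):
        df, y, signs = planted_logistic_data(8, n=3000)
        d = make_design(df)
        fit = cv_penalized_fit(d, y, "lasso", seed=8)
        lasso_rep = final_logistic_from_lasso(fit, d, y)
        plain_rep = plain_logistic_report(d, y, fit.train_idx, fit.test_idx)
        plain_tbl = plain_rep.coefficients.set_index("term")
        for term in lasso_rep.coefficients["term"]:
            if term == "intercept" or term not in plain_tbl.index:
                continue
            lcoef = lasso_rep.coefficients.set_index("term").loc[term, "coef"]
            if abs(lcoef) > 0.2:  # clearly nonzero effects keep their sign
                assert np.sign(plain_tbl.loc[term, "coef"]) == np.sign(lcoef)


class TestHosmerLemeshow:
    def test_perfectly_calibrated_groups(self):
        # predicted probability equals the observed group rate exactly
        y = np.array([1, 0, 1, 0, 1, 1, 0, 0, 1, 1] * 20, float)
        groups = np.repeat(np.arange(20), 10)
        p = np.zeros_like(y)
        for g in range(20):
            m = groups == g
            p[m] = y[m].mean()
        stat, pval = hosmer_lemeshow(y, p, groups=10)
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert pval == pytest.approx(1.0)

    def test_calibrated_simulation_accepts_at_nominal_rate(self):
        rejections = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            p = rng.uniform(0.05, 0.95, size=3000)
            y = (rng.random(3000) < p).astype(float)
            _, pval = hosmer_lemeshow(y, p)
            rejections += pval < 0.05
        assert rejections <= 3  # close to the nominal 5% level

    def test_miscalibrated_simulation_rejects(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.05, 0.7, size=3000)
        y = (rng.random(3000) < p).astype(float)
        stat, pval = hosmer_lemeshow(y, np.clip(p + 0.2, 0, 0.99))
        assert pval < 0.05

    def test_needs_enough_observations(self):
        with pytest.raises(ValueError):
            hosmer_lemeshow(np.array([1.0, 0.0]), np.array([0.5, 0.5]), groups=10)


class TestNagelkerke:
    def test_null_model_zero(self):
        assert nagelkerke_r2(-100.0, -100.0, 200) == 0.0

    def test_hand_fixture(self):
        assert nagelkerke_r2(-69.31, -59.31, 100) == pytest.approx(0.2417, abs=2e-4)

    def test_perfect_prediction_limit(self):
        assert nagelkerke_r2(-69.31, -1e-9, 100) == pytest.approx(1.0, abs=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            nagelkerke_r2(-10.0, -20.0, 100)
        with pytest.raises(ValueError):
            nagelkerke_r2(-10.0, -5.0, 0)


class TestEvaluateBinary:
    def test_metrics_bounds(self):
        rng = np.random.default_rng(0)
        y = (rng.random(500) < 0.4).astype(float)
        p = rng.random(500)
        m = evaluate_binary(y, p)
        for key in ("auc", "sensitivity", "specificity"):
            assert 0 <= m[key] <= 1
        assert m["rmse"] >= 0
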