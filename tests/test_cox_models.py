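"""Penalized Cox estimation: likelihood, lasso path, CV selection, group
lasso, prediction."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from progscape import (CoxGroupLassoCV, CoxLassoCV, PredictorMatrix,
                       cox_partial_loglik, cv_select_lambda,
                       fit_group_lasso_cox, fit_lasso_cox,
                       fit_lasso_cox_path, kkt_max_violation,
                       predict_linear_risk)
from progscape.penalized_cox import FittedPenalizedCox, as_survival

from .conftest import make_survival


def newton_cox_mle(X, time, event, iters=200):
    """Independent Newton-Raphson maximizer of the Breslow partial
    likelihood (full Hessian), used as the unpenalized-endpoint oracle."""
    X = np.asarray(X, float)
    n, p = X.shape
    order = np.argsort(time, kind="stable")
    Xs, ts, es = X[order], np.asarray(time, float)[order], \
        np.asarray(event, float)[order]
    beta = np.zeros(p)
    for _ in range(iters):
        eta = Xs @ beta
        ee = np.exp(eta - eta.max())
        grad = np.zeros(p)
        hess = np.zeros((p, p))
        uniq = np.unique(ts)
        for t in uniq:
            d_idx = np.flatnonzero((ts == t) & (es == 1))
            if d_idx.size == 0:
                continue
            r_idx = np.flatnonzero(ts >= t)
            w = ee[r_idx]
            s0 = w.sum()
            s1 = Xs[r_idx].T @ w
            s2 = (Xs[r_idx].T * w) @ Xs[r_idx]
            grad += Xs[d_idx].sum(axis=0) - d_idx.size * s1 / s0
            hess += d_idx.size * (s2 / s0 - np.outer(s1, s1) / s0**2)
        step = np.linalg.solve(hess + 1e-10 * np.eye(p), grad)
        beta = beta + step
        if np.abs(step).max() < 1e-12:
            break
    return beta


def _toy_data(seed=0, n=40, p=3, censor=0.25):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    beta = np.linspace(1.0, -1.0, p)
    t = np.exp(-(X @ beta)) * rng.exponential(size=n)
    e = (rng.uniform(size=n) > censor).astype(int)
    e[:2] = 1
    df = pd.DataFrame(X, columns=[f"x{j}" for j in range(p)],
                      index=[f"s{i}" for i in range(n)])
    return df, make_survival(t, e)


class TestPartialLoglik:
    def test_two_subject_hand_value(self):
        surv = make_survival([1.0, 2.0], [1, 1])
        assert cox_partial_loglik(np.zeros(2), surv) == \
            pytest.approx(-np.log(2.0))

    def test_location_invariance(self):
        df, surv = _toy_data(3)
        eta = df.iloc[:, 0].to_numpy()
        assert cox_partial_loglik(eta, surv) == \
            pytest.approx(cox_partial_loglik(eta + 11.3, surv))

    def test_all_censored_returns_zero_with_warning(self):
        surv = make_survival([1.0, 2.0, 3.0], [0, 0, 0])
        with pytest.warns(UserWarning, match="censored"):
            assert cox_partial_loglik(np.ones(3), surv) == 0.0


class TestLassoPath:
    def test_first_lambda_has_empty_model(self):
        df, surv = _toy_data(1)
        path = fit_lasso_cox_path(df, surv, n_lambda=30)
        assert (path.betas.iloc[0] == 0).all()
        assert path.lambdas[0] == pytest.approx(path.lambda_max)
        assert (np.diff(path.lambdas) < 0).all()

    def test_endpoint_matches_newton_mle(self):
        df, surv = _toy_data(0, n=20, p=3, censor=0.0)
        path = fit_lasso_cox_path(df, surv, n_lambda=80,
                                  lambda_min_ratio=1e-5)
        ref = newton_cox_mle(df.to_numpy(), surv.time, surv.event)
        np.testing.assert_allclose(path.betas.iloc[-1].to_numpy(), ref,
                                   atol=1e-3)

    def test_matches_lifelines_unpenalized(self):
        from lifelines import CoxPHFitter

        df, surv = _toy_data(4, n=50, p=4)
        path = fit_lasso_cox_path(df, surv, n_lambda=80,
                                  lambda_min_ratio=1e-5)
        ldf = df.copy()
        ldf["T"], ldf["E"] = surv.time, surv.event
        ref = CoxPHFitter().fit(ldf, "T", "E").params_
        np.testing.assert_allclose(path.betas.iloc[-1].to_numpy(),
                                   ref.to_numpy(), atol=2e-3)

    def test_duplicated_column_coefficients_sum_to_single_fit(self):
        df, surv = _toy_data(2, n=60, p=1)
        single = fit_lasso_cox_path(df, surv, n_lambda=40,
                                    lambda_min_ratio=0.05)
        dup = df.copy()
        dup["x0b"] = dup["x0"]
        double = fit_lasso_cox_path(dup, surv, n_lambda=40,
                                    lambda_min_ratio=0.05)
        mid = 25
        assert double.betas.iloc[mid].sum() == \
            pytest.approx(single.betas.iloc[mid, 0], abs=1e-3)

    def test_kkt_conditions_hold_at_selected_lambda(self):
        for seed in range(4):
            df, surv = _toy_data(seed, n=50, p=6)
            fit = fit_lasso_cox(df, surv, n_folds=5, seed=seed)
            assert kkt_max_violation(df, surv, fit) < 1e-4

    def test_matches_coxnet_on_standardized_data(self):
        from sksurv.linear_model import CoxnetSurvivalAnalysis

        df, surv = _toy_data(7, n=100, p=8)
        dfs = (df - df.mean()) / df.std(ddof=0)
        path = fit_lasso_cox_path(dfs, surv, n_lambda=30,
                                  lambda_min_ratio=0.05)
        y = surv.to_structured()
        ref = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=path.lambdas,
                                     tol=1e-9, max_iter=10**6)
        ref.fit(dfs.to_numpy(), y)
        np.testing.assert_allclose(path.betas.to_numpy(), ref.coef_.T,
                                   atol=0.02)


class TestCVSelection:
    def test_min_rule_never_exceeds_one_se_lambda(self):
        df, surv = _toy_data(5, n=80, p=5)
        path = fit_lasso_cox_path(df, surv, n_lambda=40)
        lam_ose = cv_select_lambda(df, surv, path, n_folds=5, rule="one_se",
                                   seed=0)
        lam_min = cv_select_lambda(df, surv, path, n_folds=5, rule="min",
                                   seed=0)
        assert lam_min <= lam_ose

    def test_pure_noise_selects_near_empty_models(self):
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(300 + rep)
            df = pd.DataFrame(rng.standard_normal((100, 10)),
                              columns=[f"x{j}" for j in range(10)],
                              index=[f"s{i}" for i in range(100)])
            t = rng.exponential(size=100)
            e = (rng.uniform(size=100) < 0.8).astype(int)
            fit = fit_lasso_cox(df, make_survival(t, e), n_folds=5,
                                seed=rep, n_lambda=40)
            hits += int(fit.model_size <= 2)
        assert hits >= 8

    def test_strong_signal_variable_is_selected(self):
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(400 + rep)
            n = 300
            df = pd.DataFrame(rng.standard_normal((n, 10)),
                              columns=[f"x{j}" for j in range(10)],
                              index=[f"s{i}" for i in range(n)])
            t = np.exp(-df["x0"].to_numpy()) * rng.exponential(size=n)
            e = (rng.uniform(size=n) < 0.8).astype(int)
            fit = fit_lasso_cox(df, make_survival(t, e), n_folds=10,
                                seed=rep, n_lambda=40)
            hits += int("x0" in fit.selected)
        assert hits >= 9


class TestGroupLasso:
    def _grouped(self, seed=0, n=120, n_groups=6, m=2):
        rng = np.random.default_rng(seed)
        cols, groups = [], []
        for g in range(n_groups):
            for j in range(m):
                cols.append(f"g{g}|m{j}")
                groups.append(f"g{g}")
        X = rng.standard_normal((n, n_groups * m))
        beta = np.zeros(n_groups * m)
        beta[:m] = 0.8
        t = np.exp(-(X @ beta)) * rng.exponential(size=n)
        e = (rng.uniform(size=n) < 0.75).astype(int)
        df = pd.DataFrame(X, columns=cols, index=[f"s{i}" for i in range(n)])
        pm = PredictorMatrix(df, group_labels=pd.Series(groups, index=cols))
        return pm, make_survival(t, e)

    def test_all_in_all_out_structure_is_exact(self):
        for seed in range(3):
            pm, surv = self._grouped(seed)
            fit = fit_group_lasso_cox(pm, surv, n_folds=5, seed=seed,
                                      n_lambda=30)
            sel = set(fit.selected)
            for g in pm.group_labels.unique():
                members = set(pm.group_labels.index[pm.group_labels == g])
                assert members <= sel or members.isdisjoint(sel)

    def test_signal_group_is_selected(self):
        pm, surv = self._grouped(11, n=200)
        fit = fit_group_lasso_cox(pm, surv, n_folds=5, seed=1, n_lambda=30)
        assert {"g0|m0", "g0|m1"} <= set(fit.selected)

    def test_singleton_groups_mimic_lasso(self):
        rng = np.random.default_rng(21)
        n, p = 150, 8
        X = rng.standard_normal((n, p))
        t = np.exp(-X[:, 0]) * rng.exponential(size=n)
        e = (rng.uniform(size=n) < 0.8).astype(int)
        df = pd.DataFrame(X, columns=[f"x{j}" for j in range(p)],
                          index=[f"s{i}" for i in range(n)])
        surv = make_survival(t, e)
        pm = PredictorMatrix(df, group_labels=pd.Series(df.columns,
                                                        index=df.columns))
        lasso = fit_lasso_cox(df, surv, n_folds=5, seed=2, n_lambda=40)
        group = fit_group_lasso_cox(pm, surv, n_folds=5, seed=2, n_lambda=40)
        assert len(set(lasso.selected) ^ set(group.selected)) <= 1

    def test_missing_group_labels_rejected(self):
        df, surv = _toy_data(1)
        with pytest.raises(ValueError, match="group_labels"):
            fit_group_lasso_cox(PredictorMatrix(df), surv)


class TestPrediction:
    def _fit(self):
        df, surv = _toy_data(6, n=60, p=3)
        return fit_lasso_cox(df, surv, n_folds=5, seed=0, n_lambda=30), df

    def test_zero_coefficients_give_constant_zero(self):
        fit, df = self._fit()
        zero = FittedPenalizedCox(fit.beta * 0.0, fit.lambda_, "lasso",
                                  fit.center, fit.scale)
        assert (predict_linear_risk(zero, df) == 0).all()

    def test_single_unit_coefficient_returns_column(self):
        fit, df = self._fit()
        beta = fit.beta * 0.0
        beta["x1"] = 1.0
        one = FittedPenalizedCox(beta, fit.lambda_, "lasso", fit.center,
                                 fit.scale)
        np.testing.assert_allclose(predict_linear_risk(one, df), df["x1"])

    def test_extra_columns_are_ignored_missing_raise(self):
        fit, df = self._fit()
        extra = df.copy()
        extra["junk"] = 1.0
        np.testing.assert_allclose(predict_linear_risk(fit, extra),
                                   predict_linear_risk(fit, df))
        with pytest.raises(ValueError, match="missing model variable"):
            predict_linear_risk(fit, df[["x0"]])

    def test_serialization_round_trip(self, tmp_path):
        fit, _ = self._fit()
        p = tmp_path / "model.tsv"
        fit.to_table(p)
        back = FittedPenalizedCox.from_table(p)
        pd.testing.assert_series_equal(back.beta, fit.beta,
                                       check_names=False)
        assert back.lambda_ == pytest.approx(fit.lambda_)
        assert back.penalty_kind == "lasso"


class TestEstimators:
    def test_lasso_estimator_fit_predict_score(self):
        df, surv = _toy_data(8, n=100, p=5)
        est = CoxLassoCV(n_lambda=30, cv=5, random_state=0)
        est.fit(df, surv.to_structured())
        assert est.coef_.shape == (5,)
        assert est.lambdas_[0] == pytest.approx(est.lambda_max_)
        risk = est.predict(df)
        assert risk.shape == (100,)
        assert 0.5 < est.score(df, surv) <= 1.0

    def test_clone_preserves_params(self):
        est = CoxLassoCV(n_lambda=17, lambda_rule="min")
        c = clone(est)
        assert c.get_params()["n_lambda"] == 17
        assert c.get_params()["lambda_rule"] == "min"

    def test_group_estimator_respects_groups(self):
        rng = np.random.default_rng(31)
        n = 120
        X = rng.standard_normal((n, 6))
        t = np.exp(-X[:, 0] - 0.5 * X[:, 1]) * rng.exponential(size=n)
        e = np.ones(n, dtype=int)
        df = pd.DataFrame(X, columns=[f"x{j}" for j in range(6)],
                          index=[f"s{i}" for i in range(n)])
        groups = ["a", "a", "b", "b", "c", "c"]
        est = CoxGroupLassoCV(groups=groups, n_lambda=25, cv=5,
                              random_state=0)
        est.fit(df, make_survival(t, e))
        sel = set(est.selected_)
        for g in set(groups):
            members = {c for c, gg in zip(df.columns, groups) if gg == g}
            assert members <= sel or members.isdisjoint(sel)

    def test_unpenalized_covariates_survive_shrinkage(self):
        df, surv = _toy_data(9, n=80, p=4)
        weights = pd.Series([1.0, 1.0, 1.0, 0.0], index=df.columns)
        fit = fit_lasso_cox(df, surv, n_folds=5, seed=0, n_lambda=30,
                            penalty_weights=weights)
        assert fit.beta["x3"] != 0.0
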