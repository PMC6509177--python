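"""Calibration methods: MAS encoding, OLS fits, epsilon-SVR and LOOCV."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from spastiq.calibrate import (
    FEATURE_COLUMNS,
    SpasticityAssessment,
    SvrConfig,
    encode_mas,
    fit_linear,
    fit_multilinear,
    fit_svr,
    loocv,
    mse,
)


class TestEncodeMas:
    @pytest.mark.parametrize(
        "grade,score", [("0", 0.0), ("1", 1.0), ("1+", 1.5), ("2", 2.0), ("3", 3.0), (0, 0.0), (2, 2.0)]
    )
    def test_mapping(self, grade, score):
        assert encode_mas(grade) == score

    @pytest.mark.parametrize("bad", ["4", 4, "2+", "", "healthy"])
    def test_unsupported_grades_rejected(self, bad):
        with pytest.raises(ValueError):
            encode_mas(bad)


class TestMse:
    def test_identical_zero(self):
        assert mse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_simple_value(self):
        assert mse([0.0, 2.0], [1.0, 1.0]) == 1.0

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=24), rng.normal(size=24)
        oracle = sum((x - y) ** 2 for x, y in zip(a, b)) / 24
        assert mse(a, b) == pytest.approx(oracle, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mse([1.0], [1.0, 2.0])


class TestLinearFits:
    def test_exact_line(self):
        x = np.arange(10.0)
        slope, inter = fit_linear(x, 2 * x + 1)
        assert (slope, inter) == (pytest.approx(2.0), pytest.approx(1.0))

    def test_centered_antisymmetric_intercept_is_mean(self):
        x = np.array([-2.0, -1.0, 1.0, 2.0])
        y = np.array([3.0, 4.0, 6.0, 7.0])
        _, inter = fit_linear(x, y)
        assert inter == pytest.approx(y.mean())

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=10), rng.normal(size=10)
        slope, inter = fit_linear(x, y)
        A = np.column_stack([x, np.ones(10)])
        ref = np.linalg.solve(A.T @ A, A.T @ y)
        assert slope == pytest.approx(ref[0], abs=1e-10)
        assert inter == pytest.approx(ref[1], abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            fit_linear([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_multilinear_irrelevant_columns_zero(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 4))
        y = 3.0 * X[:, 1] + 0.5
        coef, inter = fit_multilinear(X, y)
        assert coef[1] == pytest.approx(3.0, abs=1e-10)
        for j in (0, 2, 3):
            assert coef[j] == pytest.approx(0.0, abs=1e-10)
        assert inter == pytest.approx(0.5, abs=1e-10)

    def test_multilinear_matches_pseudoinverse_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 4))
        y = rng.normal(size=20)
        coef, inter = fit_multilinear(X, y)
        A = np.column_stack([np.ones(20), X])
        ref = np.linalg.pinv(A) @ y
        assert np.allclose(np.concatenate([[inter], coef]), ref, atol=1e-10)

    def test_multilinear_names_collinear_columns(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 3))
        X = np.column_stack([X, X[:, 0] + X[:, 1]])  # column 3 collinear
        with pytest.raises(ValueError, match=r"\[3\]"):
            fit_multilinear(X, rng.normal(size=20))


def svr_dual_oracle(X, y, cfg):
    """Dense QP solve of the epsilon-SVR dual via SLSQP on split variables.

    minimize 0.5 (a+ - a-)' K (a+ - a-) - y'(a+ - a-) + eps * sum(a+ + a-)
    subject to sum(a+ - a-) = 0 and 0 <= a+, a- <= C.
    """
    L = len(y)
    K = np.exp(-cfg.gamma * cdist(X, X, "sqeuclidean"))

    def objective(z):
        beta = z[:L] - z[L:]
        return 0.5 * beta @ K @ beta - y @ beta + cfg.epsilon * z.sum()

    def grad(z):
        beta = z[:L] - z[L:]
        g = K @ beta - y
        return np.concatenate([g + cfg.epsilon, -g + cfg.epsilon])

    cons = {"type": "eq", "fun": lambda z: z[:L].sum() - z[L:].sum()}
    bounds = [(0.0, cfg.penalty_c)] * (2 * L)
    res = minimize(
        objective,
        np.zeros(2 * L),
        jac=grad,
        bounds=bounds,
        constraints=[cons],
        method="SLSQP",
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    assert res.success, res.message
    beta = res.x[:L] - res.x[L:]
    # KKT bias from a free (strictly in-bounds) multiplier
    f0 = K @ beta
    b_vals = []
    for i in range(L):
        if 1e-6 < res.x[i] < cfg.penalty_c - 1e-6:  # a+ free: f(xi) = yi - eps
            b_vals.append(y[i] - cfg.epsilon - f0[i])
        if 1e-6 < res.x[L + i] < cfg.penalty_c - 1e-6:
            b_vals.append(y[i] + cfg.epsilon - f0[i])
    bias = float(np.mean(b_vals)) if b_vals else 0.0
    return beta, bias, objective(res.x)


class TestSvr:
    raw_cfg = SvrConfig(standardize_features=False)

    def test_defaults_match_framework_constants(self):
        cfg = SvrConfig()
        assert cfg.penalty_c == 30.0
        assert cfg.epsilon == 0.09
        assert cfg.sigma == 0.007

    def test_constant_labels_predict_constant(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(6, 5))
        model = fit_svr(X, np.full(6, 1.7), self.raw_cfg)
        assert np.allclose(model.predict(X), 1.7, atol=1e-6)
        assert np.allclose(model.predict(rng.normal(size=(3, 5))), 1.7, atol=1e-6)

    def test_dual_matches_dense_qp_oracle(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(0, 30, size=(5, 5))
        y = rng.uniform(0, 3, size=5)
        model = fit_svr(X, y, self.raw_cfg)
        beta_ref, bias_ref, obj_ref = svr_dual_oracle(X, y, self.raw_cfg)
        # map stored dual coefficients back onto training rows
        beta = np.zeros(5)
        for c, sv in zip(model.dual_coeffs, model.support_vectors):
            row = int(np.argmin(np.linalg.norm(X - sv, axis=1)))
            beta[row] = c
        assert np.allclose(beta, beta_ref, atol=1e-4)
        assert model.bias == pytest.approx(bias_ref, abs=1e-4)
        # the fit attains the dual optimum within 1e-6 on the objective
        K = np.exp(-self.raw_cfg.gamma * cdist(X, X, "sqeuclidean"))
        obj = 0.5 * beta @ K @ beta - y @ beta + self.raw_cfg.epsilon * np.abs(beta).sum()
        assert obj == pytest.approx(obj_ref, abs=1e-6)

    def test_box_constraint_respected(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(10, 5))
        y = rng.uniform(0, 3, size=10)
        model = fit_svr(X, y, self.raw_cfg)
        assert np.all(np.abs(model.dual_coeffs) <= self.raw_cfg.penalty_c + 1e-9)

    def test_duplicating_inactive_point_leaves_predictions_unchanged(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(0, 5, size=(8, 5))
        y = 0.3 * X[:, 0] + rng.normal(0, 0.02, 8)
        cfg = SvrConfig(sigma=0.05, standardize_features=False)
        model = fit_svr(X, y, cfg)
        # find a training row that is not a support vector
        d = cdist(X, model.support_vectors).min(axis=1)
        inactive = np.flatnonzero(d > 1e-9)
        if len(inactive) == 0:
            pytest.skip("all points active for this draw")
        i = inactive[0]
        X2 = np.vstack([X, X[i]])
        y2 = np.append(y, y[i])
        model2 = fit_svr(X2, y2, cfg)
        probe = rng.uniform(0, 5, size=(20, 5))
        assert np.allclose(model.predict(probe), model2.predict(probe), atol=1e-6)

    def test_training_order_invariance(self):
        rng = np.random.default_rng(9)
        X = rng.uniform(0, 30, size=(12, 5))
        y = rng.uniform(0, 3, size=12)
        perm = rng.permutation(12)
        probe = rng.uniform(0, 30, size=(5, 5))
        a = fit_svr(X, y, self.raw_cfg).predict(probe)
        b = fit_svr(X[perm], y[perm], self.raw_cfg).predict(probe)
        assert np.allclose(a, b, atol=1e-6)

    def test_standardization_statistics_from_training_data(self):
        rng = np.random.default_rng(10)
        X = rng.normal(5.0, 2.0, size=(10, 5))
        y = rng.uniform(0, 3, 10)
        model = fit_svr(X, y, SvrConfig(standardize_features=True))
        assert np.allclose(model.feature_mean, X.mean(axis=0))
        assert np.allclose(model.feature_scale, X.std(axis=0))

    def test_non_finite_features_rejected(self):
        X = np.ones((4, 5))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_svr(X, np.arange(4.0), self.raw_cfg)


def toy_features(n=10, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        rng.uniform(0.5, 1.0, size=(n, 5)), columns=list(FEATURE_COLUMNS),
        index=[f"S{i}" for i in range(n)],
    )
    df["tsrt"] = np.linspace(120, 20, n)
    return df


class TestLoocv:
    def test_perfect_linear_relation_recovered(self):
        df = toy_features()
        labels = {s: 3.0 - 0.025 * (df.loc[s, "tsrt"] - 20.0) for s in df.index}
        res = loocv(df, labels, method="lambda")
        assert res.per_method_mse["lambda"] < 1e-10

    def test_each_subject_scored_once(self):
        df = toy_features()
        labels = {s: float(i % 4) for i, s in enumerate(df.index)}
        res = loocv(df, labels, method="kinematic")
        assert sorted(res.per_subject_scores["kinematic"]) == sorted(df.index)

    def test_two_subjects_linear_degenerate_svr_valid(self):
        df = toy_features(2)
        labels = {s: float(i) for i, s in enumerate(df.index)}
        with pytest.raises(ValueError):
            loocv(df, labels, method="lambda")
        res = loocv(df, labels, method="fusion", svr_config=SvrConfig(standardize_features=False))
        assert len(res.per_subject_scores["fusion"]) == 2

    def test_held_out_label_cannot_leak(self):
        df = toy_features(8)
        labels = {s: float(i % 4) for i, s in enumerate(df.index)}
        res = loocv(df, labels, method="fusion")
        flipped = dict(labels)
        flipped["S0"] = 3.0 - flipped["S0"]  # change only the held-out label
        res2 = loocv(df, flipped, method="fusion")
        assert res.per_subject_scores["fusion"]["S0"] == pytest.approx(
            res2.per_subject_scores["fusion"]["S0"], abs=1e-12
        )

    def test_mse_recomputable_from_scores(self):
        df = toy_features(8)
        labels = {s: float(i % 4) for i, s in enumerate(df.index)}
        res = loocv(df, labels, method="lambda")
        scores = res.per_subject_scores["lambda"]
        again = mse([scores[s] for s in df.index], [labels[s] for s in df.index])
        assert res.per_method_mse["lambda"] == pytest.approx(again, abs=1e-12)


class TestSpasticityAssessment:
    def test_fit_and_summary(self):
        df = toy_features(12, seed=3)
        labels = {s: ["0", "1", "1+", "2", "3"][i % 5] for i, s in enumerate(df.index)}
        model = SpasticityAssessment(df, labels)
        pred = model.fit("lambda").predict(df[["tsrt"]].to_numpy())
        assert pred.shape == (12,)
        res = model.loocv()
        text = res.summary()
        assert "lambda" in text and "fusion" in text and "MSE" in text

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            SpasticityAssessment(pd.DataFrame({"tsrt": [1.0, 2.0]}), {"a": "0", "b": "1"})
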