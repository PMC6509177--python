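"""Calibration of biomarkers to MAS-scale scores and LOOCV evaluation.

Three supervised methods map per-subject biomarkers to a continuous score
on the modified Ashworth scale (grades 0, 1, 1+, 2, 3 encoded as 0, 1, 1.5,
2, 3):

* ``lambda``    — single-variable linear regression on the TSRT;
* ``kinematic`` — multivariate linear regression on the four kinematic
  biomarkers (three curve correlations plus acceleration MDF);
* ``fusion``    — epsilon-insensitive support vector regression with an RBF
  kernel on the concatenated five-dimensional feature vector.

Each method is scored by leave-one-out cross-validation: every subject is
predicted by a model trained on all the others, and the mean squared error
between predicted scores and clinical grades summarises performance.
Scores are continuous and deliberately unclipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.svm import SVR as _SkSVR

logger = logging.getLogger(__name__)

__all__ = [
    "MAS_NUMERIC",
    "FEATURE_COLUMNS",
    "SvrConfig",
    "SvrModel",
    "EvaluationResult",
    "SpasticityAssessment",
    "encode_mas",
    "fit_linear",
    "fit_multilinear",
    "fit_svr",
    "loocv",
    "mse",
]

MAS_NUMERIC: Mapping[str, float] = {"0": 0.0, "1": 1.0, "1+": 1.5, "2": 2.0, "3": 3.0}

#: Canonical feature order; the first column alone is the lambda method's
#: input, the last four the kinematic method's, all five the fusion's.
FEATURE_COLUMNS = ("tsrt", "corr_angle", "corr_speed", "corr_acc", "mdf_acc")

_METHOD_COLUMNS = {
    "lambda": FEATURE_COLUMNS[:1],
    "kinematic": FEATURE_COLUMNS[1:],
    "fusion": FEATURE_COLUMNS,
}


def encode_mas(grade: str | int | float) -> float:
    """Numeric encoding of a MAS grade: 0, 1, 1+, 2, 3 -> 0, 1, 1.5, 2, 3.

    Grade 4 (and anything else) is rejected: muscles that stiff cannot
    complete the passive-stretch protocol and are outside the framework.
    """
    key = str(grade).strip()
    if key in ("0.0", "1.0", "2.0", "3.0"):
        key = key[0]
    if key not in MAS_NUMERIC:
        raise ValueError(f"unsupported MAS grade {grade!r} (expected 0, 1, 1+, 2 or 3)")
    return MAS_NUMERIC[key]


def mse(scores: Sequence[float], labels: Sequence[float]) -> float:
    """Mean squared error between predicted scores and numeric grades."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.shape != labels.shape:
        raise ValueError(f"length mismatch: {scores.shape} vs {labels.shape}")
    if scores.size == 0:
        raise ValueError("mse undefined on empty inputs")
    return float(np.mean((labels - scores) ** 2))


def fit_linear(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Simple OLS; returns (slope, intercept).  Predictions are unclipped."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 points")
    xm = x.mean()
    sxx = np.sum((x - xm) ** 2)
    if sxx == 0:
        raise ValueError("zero variance in the predictor")
    slope = float(np.sum((x - xm) * (y - y.mean())) / sxx)
    return slope, float(y.mean() - slope * xm)


def fit_multilinear(X: np.ndarray, y: Sequence[float]) -> tuple[np.ndarray, float]:
    """Multivariate OLS; returns (coefficients, intercept).

    Raises on a rank-deficient design, naming the columns that are linear
    combinations of the preceding ones.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more rows ({n}) than columns ({p})")
    A = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(A)
    if rank < p + 1:
        bad = []
        for j in range(1, p + 1):
            if np.linalg.matrix_rank(A[:, : j + 1]) == np.linalg.matrix_rank(A[:, :j]):
                bad.append(j - 1)
        raise ValueError(f"rank-deficient design: collinear columns {bad}")
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return beta[1:], float(beta[0])


@dataclass(frozen=True)
class SvrConfig:
    """SVR hyperparameters for the fusion method.

    Defaults are the framework's empirical settings: penalty C = 30,
    tube half-width epsilon = 0.09 (score units) and kernel parameter
    sigma = 0.007.  ``kernel_form`` selects how sigma enters the RBF
    kernel: ``"gamma"`` (default) reads it as an inverse squared length
    scale, kappa = exp(-sigma * ||x - x'||^2), the libsvm convention;
    ``"bandwidth"`` reads it as a length scale,
    kappa = exp(-||x - x'||^2 / (2 sigma^2)).  ``standardize_features``
    (default on, standard practice ahead of an RBF kernel) z-scores the
    features, with statistics taken from the training fold only.
    """

    penalty_c: float = 30.0
    epsilon: float = 0.09
    sigma: float = 0.007
    kernel_form: str = "gamma"
    standardize_features: bool = True

    def __post_init__(self) -> None:
        if self.penalty_c <= 0:
            raise ValueError("penalty_c must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.kernel_form not in ("gamma", "bandwidth"):
            raise ValueError("kernel_form must be 'gamma' or 'bandwidth'")

    @property
    def gamma(self) -> float:
        """RBF gamma such that kappa = exp(-gamma * ||x - x'||^2)."""
        if self.kernel_form == "gamma":
            return self.sigma
        return 1.0 / (2.0 * self.sigma**2)


@dataclass
class SvrModel:
    """Fitted epsilon-SVR in its dual form.

    Prediction is f(x) = sum_i beta_i * kappa(x, x_i) + b over the support
    vectors, with beta_i the dual-coefficient differences bounded by the box
    constraint |beta_i| <= C.
    """

    dual_coeffs: np.ndarray
    bias: float
    support_vectors: np.ndarray
    gamma: float
    config: SvrConfig
    feature_mean: np.ndarray | None = None
    feature_scale: np.ndarray | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.feature_mean is not None:
            X = (X - self.feature_mean) / self.feature_scale
        K = np.exp(-self.gamma * cdist(X, self.support_vectors, "sqeuclidean"))
        return K @ self.dual_coeffs + self.bias


def fit_svr(X: np.ndarray, y: Sequence[float], cfg: SvrConfig | None = None) -> SvrModel:
    """Fit epsilon-insensitive SVR with an RBF kernel.

    Solves the standard dual (box constraint [0, C] on each multiplier
    pair, KKT-consistent bias) via libsvm with a tight stopping tolerance;
    the returned model predicts from its stored dual coefficients.
    """
    cfg = cfg or SvrConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite features or labels")
    if len(X) < 1:
        raise ValueError("need at least 1 training sample")

    mean = scale = None
    if cfg.standardize_features:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale == 0, 1.0, scale)
        X = (X - mean) / scale

    sk = _SkSVR(kernel="rbf", gamma=cfg.gamma, C=cfg.penalty_c, epsilon=cfg.epsilon, tol=1e-9)
    sk.fit(X, y)
    return SvrModel(
        dual_coeffs=sk.dual_coef_.ravel().copy(),
        bias=float(sk.intercept_[0]),
        support_vectors=sk.support_vectors_.copy(),
        gamma=cfg.gamma,
        config=cfg,
        feature_mean=mean,
        feature_scale=scale,
    )


@dataclass
class EvaluationResult:
    """LOOCV outcome: per-subject scores and per-method MSE against MAS."""

    per_subject_scores: dict[str, dict[str, float]]
    per_method_mse: dict[str, float]
    labels: dict[str, float]
    excluded: dict[str, str] = field(default_factory=dict)

    def scores_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.per_subject_scores)
        df["mas"] = pd.Series(self.labels)
        return df.sort_index()

    def regression_line(self, method: str) -> tuple[float, float]:
        """OLS line of predicted scores against true grades for a method."""
        scores = self.per_subject_scores[method]
        ids = sorted(scores)
        return fit_linear([self.labels[s] for s in ids], [scores[s] for s in ids])

    def summary(self) -> str:
        lines = ["Leave-one-out evaluation", "=" * 52]
        lines.append(f"{'method':<12}{'MSE':>10}{'score = a*MAS + b':>26}")
        for method, err in self.per_method_mse.items():
            a, b = self.regression_line(method)
            lines.append(f"{method:<12}{err:>10.4f}{f'y = {a:.3f}x + {b:.3f}':>26}")
        n = len(self.labels)
        lines.append(f"subjects scored: {n}; excluded: {len(self.excluded)}")
        return "\n".join(lines)


def _train_predict(
    method: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    svr_config: SvrConfig,
) -> np.ndarray:
    if method == "lambda":
        slope, inter = fit_linear(X_train[:, 0], y_train)
        return slope * X_test[:, 0] + inter
    if method == "kinematic":
        coef, inter = fit_multilinear(X_train, y_train)
        return X_test @ coef + inter
    if method == "fusion":
        return fit_svr(X_train, y_train, svr_config).predict(X_test)
    raise ValueError(f"unknown method {method!r}")


def loocv(
    features: pd.DataFrame,
    labels: Mapping[str, float],
    method: str = "fusion",
    svr_config: SvrConfig | None = None,
    result: EvaluationResult | None = None,
) -> EvaluationResult:
    """Leave-one-out cross-validation for one method.

    ``features`` is indexed by subject_id with the five biomarker columns
    (``FEATURE_COLUMNS``); the method selects its own column subset.  Each
    subject is scored by a model trained on all the others; scores are
    unclipped.  Pass an existing ``result`` to accumulate several methods
    into one object.
    """
    svr_config = svr_config or SvrConfig()
    cols = list(_METHOD_COLUMNS[method])
    ids = [s for s in features.index if s in labels]
    if len(ids) < 2:
        raise ValueError("need at least 2 subjects for leave-one-out")
    X = features.loc[ids, cols].to_numpy(dtype=float)
    y = np.array([labels[s] for s in ids], dtype=float)
    if not np.isfinite(X).all():
        bad = [ids[i] for i in np.unique(np.nonzero(~np.isfinite(X))[0])]
        raise ValueError(f"non-finite features for subjects {bad}")

    scores: dict[str, float] = {}
    for i, sid in enumerate(ids):
        keep = np.arange(len(ids)) != i
        pred = _train_predict(method, X[keep], y[keep], X[i : i + 1], svr_config)
        scores[sid] = float(pred[0])

    err = mse([scores[s] for s in ids], y)
    if result is None:
        result = EvaluationResult(
            per_subject_scores={}, per_method_mse={}, labels={s: float(labels[s]) for s in ids}
        )
    result.per_subject_scores[method] = scores
    result.per_method_mse[method] = err
    return result


class SpasticityAssessment:
    """Calibration model over a cohort's biomarkers and clinical grades.

    Parameters
    ----------
    features : DataFrame indexed by subject_id with columns
        ``('tsrt', 'corr_angle', 'corr_speed', 'corr_acc', 'mdf_acc')``.
    labels : mapping or Series of subject_id -> MAS grade (categorical
        strings or numeric encodings).

    ``fit(method)`` trains the chosen calibration on the full cohort and
    returns a predictor; ``loocv(methods)`` runs the leave-one-out
    evaluation and returns an :class:`EvaluationResult`.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        labels: Mapping[str, str | float] | pd.Series,
        svr_config: SvrConfig | None = None,
    ):
        missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
        if missing:
            raise ValueError(f"features missing columns {missing}")
        self.features = features.loc[:, list(FEATURE_COLUMNS)].copy()
        self.labels = {str(s): encode_mas(g) for s, g in dict(labels).items()}
        self.svr_config = svr_config or SvrConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_column: str = "mas_grade",
                       svr_config: SvrConfig | None = None) -> "SpasticityAssessment":
        labels = df[label_column].to_dict()
        return cls(df, labels, svr_config=svr_config)

    def fit(self, method: str = "fusion"):
        """Train on the full cohort; returns an object with ``.predict``."""
        cols = list(_METHOD_COLUMNS[method])
        ids = [s for s in self.features.index if s in self.labels]
        X = self.features.loc[ids, cols].to_numpy(dtype=float)
        y = np.array([self.labels[s] for s in ids])
        if method == "lambda":
            slope, inter = fit_linear(X[:, 0], y)
            return _LinearPredictor(np.array([slope]), inter, cols)
        if method == "kinematic":
            coef, inter = fit_multilinear(X, y)
            return _LinearPredictor(coef, inter, cols)
        if method == "fusion":
            return fit_svr(X, y, self.svr_config)
        raise ValueError(f"unknown method {method!r}")

    def loocv(self, methods: Sequence[str] = ("lambda", "kinematic", "fusion")) -> EvaluationResult:
        result: EvaluationResult | None = None
        for method in methods:
            result = loocv(self.features, self.labels, method, self.svr_config, result)
        assert result is not None
        return result


@dataclass
class _LinearPredictor:
    coef: np.ndarray
    intercept: float
    columns: list[str]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.coef + self.intercept
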