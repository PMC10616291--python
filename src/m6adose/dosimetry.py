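"""Absorbed-dose reconstruction from m6A biomarker levels.

Inverse-regression calibration: the absorbed dose (Gy) is regressed on the
observed m6A level — per timepoint with a quadratic in the level, or jointly
with a bivariate cubic in (level, time post irradiation).  Model quality is
the coefficient of determination on training data; classification utility at
a dose cutoff is quantified by rank-based ROC AUC of the model-predicted
doses, apparent or under repeated stratified k-fold cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.utils.validation import check_is_fitted
from scipy import stats

__all__ = [
    "QuadraticDoseModel",
    "BivariateCubicDoseModel",
    "ROCEvaluation",
    "fit_per_tpi_quadratic",
    "fit_bivariate_cubic",
    "predict_dose",
    "r_squared",
    "roc_auc",
    "evaluate_cutoff",
    "repeated_cv_auc",
    "confidence_band",
]

# exponent pairs (i, j) for m^i * t^j, total degree <= 3, in documented order
_EXPONENTS_TOTAL = (
    (0, 0), (1, 0), (0, 1), (2, 0), (1, 1), (0, 2), (3, 0), (2, 1), (1, 2), (0, 3),
)
_EXPONENTS_TENSOR = tuple((i, j) for i in range(4) for j in range(4))


def _design_matrix_quadratic(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float).ravel()
    return np.column_stack([np.ones_like(m), m, m**2])


def _design_matrix_bivariate(m, t, basis: str = "total") -> np.ndarray:
    m = np.asarray(m, dtype=float).ravel()
    t = np.asarray(t, dtype=float).ravel()
    exps = _EXPONENTS_TOTAL if basis == "total" else _EXPONENTS_TENSOR
    if basis not in ("total", "tensor"):
        raise ValueError("basis must be 'total' or 'tensor'")
    return np.column_stack([m**i * t**j for i, j in exps])


def _term_names(basis: str) -> list[str]:
    exps = _EXPONENTS_TOTAL if basis == "total" else _EXPONENTS_TENSOR
    return [f"m^{i}*t^{j}" for i, j in exps]


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a maximal independent column subset greedily; the rest
        # are the (numerically) dependent terms worth naming in the error
        keep: list[int] = []
        for j in range(X.shape[1]):
            trial = X[:, keep + [j]]
            if np.linalg.matrix_rank(trial) > len(keep):
                keep.append(j)
        dependent = [names[j] for j in range(X.shape[1]) if j not in keep]
        raise ValueError(
            f"rank-deficient design (rank {rank} < {X.shape[1]}); "
            f"linearly dependent terms: {dependent}"
        )


def _ols(X: np.ndarray, y: np.ndarray):
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    df_resid = X.shape[0] - X.shape[1]
    sigma2 = ss_res / df_resid if df_resid > 0 else np.nan
    xtx_inv = np.linalg.pinv(X.T @ X)
    return coef, r2, sigma2, xtx_inv, df_resid


class QuadraticDoseModel(RegressorMixin, BaseEstimator):
    """Per-timepoint quadratic calibration: dose = b0 + b1 m + b2 m^2.

    Fit by ordinary least squares of dose on (1, m, m^2) for observations
    sharing one time post irradiation.  Fitted attributes: ``coef_`` (b0,
    b1, b2), ``r2_`` (training R^2), ``n_train_``, ``tpi_days_``,
    ``cov_params_`` and ``df_resid_`` (for confidence bands).
    """

    kind = "per_tpi_quadratic"

    def __init__(self, tpi_days: float | None = None):
        self.tpi_days = tpi_days

    def fit(self, X, y):
        m = np.asarray(X, dtype=float).ravel()
        dose = np.asarray(y, dtype=float).ravel()
        if m.size != dose.size:
            raise ValueError("m6A values and doses must align")
        if m.size < 3 or len(np.unique(m)) < 3:
            raise ValueError("quadratic fit needs >= 3 points with >= 3 distinct m6A values")
        Xd = _design_matrix_quadratic(m)
        _check_full_rank(Xd, ["1", "m", "m^2"])
        coef, r2, sigma2, xtx_inv, df_resid = _ols(Xd, dose)
        self.coef_ = coef
        self.r2_ = r2
        self.n_train_ = int(m.size)
        self.tpi_days_ = self.tpi_days
        self.cov_params_ = sigma2 * xtx_inv
        self.df_resid_ = df_resid
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        return _design_matrix_quadratic(np.asarray(X, dtype=float).ravel()) @ self.coef_

    def to_dict(self) -> dict:
        check_is_fitted(self, "coef_")
        return {
            "kind": self.kind,
            "coefficient_order": ["1", "m", "m^2"],
            "coefficients": self.coef_.tolist(),
            "tpi_days": self.tpi_days_,
            "r2": self.r2_,
            "n_train": self.n_train_,
        }


class BivariateCubicDoseModel(RegressorMixin, BaseEstimator):
    """Integrated calibration: dose as a bivariate cubic in (m6A level, TPI).

    The default basis is all 10 monomials m^i t^j of total degree i + j <= 3
    (the standard reading of a bivariate cubic); ``basis='tensor'`` switches
    to the 16-term basis of degree <= 3 in each variable.  Fit by ordinary
    least squares; a rank-deficient design (e.g. every point at one TPI)
    raises an error naming the dependent terms.
    """

    kind = "bivariate_cubic"

    def __init__(self, basis: str = "total"):
        self.basis = basis

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        dose = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have two columns: m6A value and TPI (days)")
        n_terms = 10 if self.basis == "total" else 16
        if X.shape[0] < n_terms:
            raise ValueError(f"bivariate cubic fit needs >= {n_terms} points")
        Xd = _design_matrix_bivariate(X[:, 0], X[:, 1], basis=self.basis)
        _check_full_rank(Xd, _term_names(self.basis))
        coef, r2, sigma2, xtx_inv, df_resid = _ols(Xd, dose)
        self.coef_ = coef
        self.r2_ = r2
        self.n_train_ = int(X.shape[0])
        self.cov_params_ = sigma2 * xtx_inv
        self.df_resid_ = df_resid
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        return _design_matrix_bivariate(X[:, 0], X[:, 1], basis=self.basis) @ self.coef_

    def to_dict(self) -> dict:
        check_is_fitted(self, "coef_")
        return {
            "kind": self.kind,
            "basis": self.basis,
            "coefficient_order": _term_names(self.basis),
            "coefficients": self.coef_.tolist(),
            "r2": self.r2_,
            "n_train": self.n_train_,
        }


# ---------------------------------------------------------------------------
# Functional surface over the estimators
# ---------------------------------------------------------------------------


def fit_per_tpi_quadratic(points: pd.DataFrame) -> QuadraticDoseModel:
    """Fit the quadratic dose model on points sharing one TPI.

    ``points`` needs columns m6a_value, tpi_days, dose_gy; mixed TPIs raise.
    """
    tps = points["tpi_days"].unique()
    if len(tps) != 1:
        raise ValueError(f"per-TPI fit requires a single TPI, got {sorted(tps)}")
    model = QuadraticDoseModel(tpi_days=float(tps[0]))
    return model.fit(points["m6a_value"].to_numpy(), points["dose_gy"].to_numpy())


def fit_bivariate_cubic(points: pd.DataFrame, basis: str = "total") -> BivariateCubicDoseModel:
    """Fit the integrated (m6A, TPI) -> dose model on points spanning >= 2 TPIs."""
    model = BivariateCubicDoseModel(basis=basis)
    X = points[["m6a_value", "tpi_days"]].to_numpy(dtype=float)
    return model.fit(X, points["dose_gy"].to_numpy(dtype=float))


def predict_dose(model, m6a_value, tpi_days=None, clamp_at_zero: bool = False):
    """Evaluate a fitted dose model; negative estimates reported as-is unless clamped.

    Returns (estimates, negative_flags).
    """
    if model.kind == "bivariate_cubic":
        if tpi_days is None:
            raise ValueError("the bivariate cubic model requires tpi_days")
        m = np.asarray(m6a_value, dtype=float).ravel()
        t = np.broadcast_to(np.asarray(tpi_days, dtype=float), m.shape).ravel()
        pred = model.predict(np.column_stack([m, t]))
    else:
        pred = model.predict(np.asarray(m6a_value, dtype=float).ravel())
    negative = pred < 0
    if clamp_at_zero:
        pred = np.clip(pred, 0.0, None)
    return pred, negative


def confidence_band(model, X, level: float = 0.95) -> pd.DataFrame:
    """Pointwise confidence band for the fitted mean dose curve/surface.

    Uses the least-squares covariance of the coefficients: halfwidth =
    t_{df, 1-(1-level)/2} * sqrt(x' cov x) at each evaluation point.
    """
    check_is_fitted(model, "coef_")
    X = np.asarray(X, dtype=float)
    if model.kind == "bivariate_cubic":
        Xd = _design_matrix_bivariate(X[:, 0], X[:, 1], basis=model.basis)
    else:
        Xd = _design_matrix_quadratic(X.ravel())
    mean = Xd @ model.coef_
    se = np.sqrt(np.einsum("ij,jk,ik->i", Xd, model.cov_params_, Xd))
    tq = stats.t.ppf(1 - (1 - level) / 2, model.df_resid_)
    return pd.DataFrame({"predicted_dose": mean, "lower": mean - tq * se, "upper": mean + tq * se})


def r_squared(actual, predicted) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (can be negative)."""
    a = np.asarray(actual, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if a.size != p.size:
        raise ValueError("actual and predicted must align")
    if a.size < 2:
        raise ValueError("need at least 2 points")
    ss_tot = float(((a - a.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("zero variance in actual doses")
    return 1.0 - float(((a - p) ** 2).sum()) / ss_tot


def roc_auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) ROC AUC; ties credited 0.5.

    Equals the fraction of positive-negative pairs where the positive
    outscores the negative, counting ties as half.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).astype(int).ravel()
    if scores.size != labels.size:
        raise ValueError("scores and labels must align")
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, scores))


# ---------------------------------------------------------------------------
# Cutoff classification with repeated cross-validation
# ---------------------------------------------------------------------------


@dataclass
class ROCEvaluation:
    cutoff_gy: float
    auc: float  # apparent (fit on all points)
    cv_mean_auc: float | None = None
    cv_sd: float | None = None
    k: int | None = None
    reps: int | None = None
    seed: int | None = None


def _make_model(model_spec: str, basis: str = "total"):
    if model_spec == "bivariate_cubic":
        return BivariateCubicDoseModel(basis=basis)
    if model_spec == "per_tpi_quadratic":
        return QuadraticDoseModel()
    raise ValueError(f"unknown model spec {model_spec!r}")


def _features(points: pd.DataFrame, model_spec: str) -> np.ndarray:
    if model_spec == "bivariate_cubic":
        return points[["m6a_value", "tpi_days"]].to_numpy(dtype=float)
    return points[["m6a_value"]].to_numpy(dtype=float)


def _cutoff_labels(points: pd.DataFrame, cutoff_gy: float) -> np.ndarray:
    doses = points["dose_gy"].to_numpy(dtype=float)
    if not doses.min() < cutoff_gy <= doses.max():
        raise ValueError(
            f"cutoff {cutoff_gy} Gy outside the observed dose range "
            f"({doses.min():g}, {doses.max():g}]"
        )
    return (doses >= cutoff_gy).astype(int)


def _strata(points: pd.DataFrame, stratify_by: str) -> np.ndarray:
    if stratify_by == "group":
        return (
            points["dose_gy"].astype(str) + "|" + points["tpi_days"].astype(str)
        ).to_numpy()
    if stratify_by == "subject":
        return points["subject_id"].to_numpy()
    if stratify_by == "none":
        return np.zeros(len(points))
    raise ValueError("stratify_by must be 'group', 'subject' or 'none'")


def repeated_cv_auc(
    points: pd.DataFrame,
    cutoff_gy: float,
    model_spec: str = "bivariate_cubic",
    k: int = 5,
    reps: int = 100,
    seed: int = 0,
    stratify_by: str = "group",
    basis: str = "total",
) -> tuple[float, float, np.ndarray]:
    """Mean and SD of the per-repetition pooled-prediction AUC.

    Each repetition draws a fresh stratified k-fold partition (strata =
    (dose, TPI) groups by default, so every fold sees the full dose range),
    fits the dose model on k-1 folds, predicts the held-out fold, pools the
    held-out predictions, and computes the AUC at the cutoff.  Repetition r
    uses the RNG stream SeedSequence(seed, spawn_key=(r,)), so extending
    ``reps`` preserves the prefix of per-repetition AUCs.

    Returns (mean, sd, per-repetition AUC array).
    """
    n = len(points)
    if n < k:
        raise ValueError("fewer points than folds")
    labels = _cutoff_labels(points, cutoff_gy)
    strata = _strata(points, stratify_by)
    X = _features(points, model_spec)
    y = points["dose_gy"].to_numpy(dtype=float)

    codes, counts = np.unique(strata, return_counts=True)
    stratified = counts.min() >= k
    if not stratified and stratify_by != "none":
        # degrade gracefully: plain shuffled k-fold when strata are thinner
        # than the fold count
        warnings.warn(
            "some strata have fewer members than folds; using unstratified k-fold",
            RuntimeWarning,
        )

    aucs = np.empty(reps)
    for rep in range(reps):
        rs = int(np.random.SeedSequence(int(seed), spawn_key=(rep,)).generate_state(1)[0] % (2**31))
        pred = np.empty(n)
        if stratified:
            splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=rs)
            split = splitter.split(X, strata)
        else:
            splitter = KFold(n_splits=k, shuffle=True, random_state=rs)
            split = splitter.split(X)
        for train, test in split:
            model = _make_model(model_spec, basis)
            model.fit(X[train], y[train])
            pred[test] = model.predict(X[test])
        aucs[rep] = roc_auc(pred, labels)
    return float(aucs.mean()), float(aucs.std(ddof=1)) if reps > 1 else 0.0, aucs


def evaluate_cutoff(
    points: pd.DataFrame,
    cutoff_gy: float,
    model_spec: str = "bivariate_cubic",
    cv: dict | None = None,
    basis: str = "total",
) -> ROCEvaluation:
    """Apparent (and optionally cross-validated) AUC at a dose cutoff.

    Scores are model-predicted doses; positives are points with actual dose
    >= cutoff.  ``cv`` is an optional dict with keys k, reps, seed,
    stratify_by forwarded to :func:`repeated_cv_auc`.
    """
    labels = _cutoff_labels(points, cutoff_gy)
    X = _features(points, model_spec)
    y = points["dose_gy"].to_numpy(dtype=float)
    model = _make_model(model_spec, basis)
    model.fit(X, y)
    apparent = roc_auc(model.predict(X), labels)
    if cv is None:
        return ROCEvaluation(cutoff_gy=cutoff_gy, auc=apparent)
    mean, sd, _ = repeated_cv_auc(
        points,
        cutoff_gy,
        model_spec=model_spec,
        k=cv.get("k", 5),
        reps=cv.get("reps", 100),
        seed=cv.get("seed", 0),
        stratify_by=cv.get("stratify_by", "group"),
        basis=basis,
    )
    return ROCEvaluation(
        cutoff_gy=cutoff_gy,
        auc=apparent,
        cv_mean_auc=mean,
        cv_sd=sd,
        k=cv.get("k", 5),
        reps=cv.get("reps", 100),
        seed=cv.get("seed", 0),
    )
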