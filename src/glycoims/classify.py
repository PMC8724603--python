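"""Sparse logistic classification of tumor vs adjacent-normal cores.

An L1-penalized (LASSO) logistic regression fitted by cyclic coordinate
descent on the iteratively-reweighted-least-squares quadratic
approximation, with soft-thresholding.  The objective is

    (1/n) * sum_i [log(1 + exp(eta_i)) - y_i * eta_i] + lambda * ||beta||_1

over features standardized to zero mean and unit variance, with an
unpenalized intercept — the convention under which penalty weights
(lambda) have a stable scale across datasets.  The tumor class is the
positive class throughout.

The solver is written here rather than delegated: exact zeros from the
soft-threshold operator, the lambda_max identity, and the regularization
path are part of the module's contract and are tested against
closed-form and unpenalized oracles.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_MIN_WEIGHT = 1e-5  # floor on IRLS weights, as in standard GLM practice


@dataclass
class LassoModel:
    """A fitted sparse logistic model with its standardization context."""

    feature_names: list[str]
    coefficients: np.ndarray  # on the standardized scale
    intercept: float
    lam: float
    alpha: float = 1.0  # elastic-net mixing; fixed at 1 (pure LASSO)
    means: np.ndarray = field(default_factory=lambda: np.array([]))
    scales: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def selected_features(self) -> list[str]:
        return [f for f, c in zip(self.feature_names, self.coefficients) if c != 0.0]

    def to_json(self, path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "lambda": self.lam,
            "alpha": self.alpha,
            "means": self.means.tolist(),
            "scales": self.scales.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "LassoModel":
        with open(path) as fh:
            p = json.load(fh)
        return cls(
            feature_names=p["feature_names"],
            coefficients=np.asarray(p["coefficients"]),
            intercept=p["intercept"],
            lam=p["lambda"],
            alpha=p.get("alpha", 1.0),
            means=np.asarray(p["means"]),
            scales=np.asarray(p["scales"]),
        )


@dataclass
class RocResult:
    """An ROC curve with its trapezoidal area."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def _soft_threshold(z: float, gamma: float) -> float:
    if z > gamma:
        return z - gamma
    if z < -gamma:
        return z + gamma
    return 0.0


def _standardize(X: np.ndarray):
    means = X.mean(axis=0)
    scales = X.std(axis=0)  # population sd
    if np.any(scales <= 0):
        bad = np.flatnonzero(scales <= 0)
        raise ValueError(f"constant feature column(s) at index {bad.tolist()}")
    return (X - means) / scales, means, scales


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which all slope coefficients are zero.

    With standardized features, an intercept at the empirical logit and
    all slopes zero, the coordinate-wise stationarity condition gives
    max_j |X_std^T (y - ybar)| / n.
    """
    Xs, _, _ = _standardize(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    return float(np.max(np.abs(Xs.T @ (y - y.mean())) / y.size))


def fit_lasso_logistic(
    X,
    y,
    lam: float,
    feature_names: list[str] | None = None,
    max_iter: int = 200,
    tol: float = 1e-7,
    warm_start: tuple[np.ndarray, float] | None = None,
) -> LassoModel:
    """Fit the L1-penalized logistic regression at penalty ``lam``.

    Outer IRLS iterations form a weighted least-squares approximation at
    the current linear predictor; inner cyclic coordinate descent with
    soft-thresholding solves it.  Converged when the largest coefficient
    change across an outer iteration falls below ``tol``.  ``warm_start``
    is an optional ``(beta, intercept)`` on the standardized scale, used
    when walking a descending lambda path.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    for cls in (0.0, 1.0):
        if (y == cls).sum() < 2:
            raise ValueError("need at least 2 cores per class")
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(p)]
    Xs, means, scales = _standardize(X)

    if warm_start is not None:
        beta = np.array(warm_start[0], dtype=float)
        b0 = float(warm_start[1])
    else:
        beta = np.zeros(p)
        b0 = float(np.log(y.mean() / (1 - y.mean())))  # logit of prevalence
    eta = b0 + Xs @ beta

    for _ in range(max_iter):
        prob = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(prob * (1.0 - prob), _MIN_WEIGHT, None)
        z = eta + (y - prob) / w  # working response

        beta_old = beta.copy()
        b0_old = b0
        # inner cyclic coordinate descent on the quadratic approximation
        for _inner in range(100):
            max_delta = 0.0
            r = z - b0 - Xs @ beta  # working residual
            for j in range(p):
                bj = beta[j]
                rho = (w * Xs[:, j] * (r + Xs[:, j] * bj)).sum() / n
                denom = (w * Xs[:, j] ** 2).sum() / n
                new = _soft_threshold(rho, lam) / denom
                if new != bj:
                    r += Xs[:, j] * (bj - new)
                    beta[j] = new
                    max_delta = max(max_delta, abs(new - bj))
            new_b0 = b0 + (w * r).sum() / w.sum()
            r += b0 - new_b0
            max_delta = max(max_delta, abs(new_b0 - b0))
            b0 = new_b0
            if max_delta < tol:
                break
        eta = b0 + Xs @ beta
        if max(np.max(np.abs(beta - beta_old)), abs(b0 - b0_old)) < tol:
            break
    else:
        raise RuntimeError(
            "coordinate descent did not converge in "
            f"{max_iter} IRLS iterations (last change "
            f"{max(np.max(np.abs(beta - beta_old)), abs(b0 - b0_old)):.3e})"
        )

    if lam == 0.0 and np.max(np.abs(beta)) > 50:
        logger.warning(
            "possible perfect separation at lambda=0: max |beta| = %.1f",
            float(np.max(np.abs(beta))),
        )
    return LassoModel(
        feature_names=list(feature_names),
        coefficients=beta,
        intercept=b0,
        lam=lam,
        means=means,
        scales=scales,
    )


def predict_prob(model: LassoModel, X, feature_names: list[str] | None = None) -> np.ndarray:
    """Per-core tumor probability under a fitted model.

    Raw features are standardized with the means/scales stored at fit
    time, so predictions are invariant to affine rescaling of inputs
    refitted under the same pipeline.
    """
    if isinstance(X, pd.DataFrame):
        missing = [f for f in model.feature_names if f not in X.columns]
        if missing:
            raise ValueError(f"missing feature column(s): {missing}")
        X = X[model.feature_names].to_numpy(dtype=float)
    elif feature_names is not None:
        if list(feature_names) != list(model.feature_names):
            raise ValueError("feature names do not align with model")
        X = np.asarray(X, dtype=float)
    else:
        X = np.asarray(X, dtype=float)
    if model.means.size:
        X = (X - model.means) / model.scales
    eta = model.intercept + X @ model.coefficients
    return 1.0 / (1.0 + np.exp(-eta))


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


def default_lambda_grid(X, y, n_lambda: int = 25, ratio: float = 0.01) -> np.ndarray:
    """Log-spaced grid from lambda_max down to ratio * lambda_max."""
    lmax = lambda_max(X, y)
    return np.geomspace(lmax, ratio * lmax, n_lambda)


def _stratified_folds(
    X: np.ndarray, y: np.ndarray, n_folds: int, rng: np.random.Generator
):
    """Class-stratified folds; identical rows stay in the same fold.

    Keeping duplicate observations together prevents leakage of a row
    into both the training and held-out sides of a split, and makes the
    selected lambda invariant to duplicating the dataset (training on a
    duplicated set has the same minimizer; held-out deviance scales
    uniformly).
    """
    folds = [[] for _ in range(n_folds)]
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        groups: dict[bytes, list[int]] = {}
        for i in idx:
            groups.setdefault(X[i].tobytes(), []).append(int(i))
        keys = list(groups)
        order = rng.permutation(len(keys))
        for k, gi in enumerate(order):
            folds[k % n_folds].extend(groups[keys[gi]])
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def cv_lambda(
    X,
    y,
    lambdas=None,
    n_folds: int = 10,
    seed: int = 0,
) -> float:
    """Select lambda by stratified cross-validated binomial deviance.

    Folds are stratified by class; should a fold still end up one-class
    (tiny data), folds are redrawn with a warning.  Deterministic given
    ``seed``.  Returns the grid value minimizing mean held-out deviance.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if lambdas is None:
        lambdas = default_lambda_grid(X, y)
    lambdas = np.atleast_1d(np.asarray(lambdas, dtype=float))
    if lambdas.size == 1:
        return float(lambdas[0])

    rng = np.random.default_rng(seed)
    for attempt in range(10):
        folds = _stratified_folds(X, y, n_folds, rng)
        if all(len(np.unique(y[f])) == 2 or len(f) == 0 for f in folds):
            break
        logger.warning("cv_lambda: one-class fold, redrawing folds")
    # walk each fold's descending lambda path with warm starts
    order = np.argsort(-lambdas, kind="stable")
    deviance = np.zeros(lambdas.size)
    for fold in folds:
        if len(fold) == 0:
            continue
        mask = np.ones(y.size, dtype=bool)
        mask[fold] = False
        warm = None
        for li in order:
            m = fit_lasso_logistic(X[mask], y[mask], lambdas[li], warm_start=warm)
            warm = (m.coefficients, m.intercept)
            p = np.clip(predict_prob(m, X[fold]), 1e-10, 1 - 1e-10)
            deviance[li] += -2.0 * np.sum(
                y[fold] * np.log(p) + (1 - y[fold]) * np.log(1 - p)
            )
    best = int(np.argmin(deviance))
    return float(lambdas[best])


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------


def roc(scores, labels) -> RocResult:
    """ROC curve over all score thresholds, with trapezoidal AUC.

    The AUC equals the Mann–Whitney probability that a random positive
    scores above a random negative, counting ties as one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    l = labels[order]
    # collapse tied scores into single thresholds
    distinct = np.r_[True, np.diff(s) != 0]
    tp = np.cumsum(l)
    fp = np.cumsum(1 - l)
    idx = np.flatnonzero(np.r_[distinct[1:], True])
    tpr = np.r_[0.0, tp[idx] / n_pos]
    fpr = np.r_[0.0, fp[idx] / n_neg]
    thresholds = np.r_[np.inf, s[idx]]
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


def combined_vs_single(
    X_bio: pd.DataFrame,
    X_mass: pd.DataFrame,
    y,
    lam: float | str | dict = "cv",
    seed: int = 0,
) -> dict[str, RocResult]:
    """Fit and evaluate biomarker-only, mass-only, and combined models.

    All three models are fitted and scored on the same cores; the penalty
    is a fixed value, ``"cv"`` for per-model cross-validation, or a dict
    mapping model name to either.  Returns
    {"biomarker": ..., "mass": ..., "combined": ...}.
    """
    if not X_bio.index.equals(X_mass.index):
        raise ValueError("biomarker and mass tables must share the same core set")
    y = np.asarray(y, dtype=float)
    X_comb = pd.concat([X_bio, X_mass], axis=1)
    out = {}
    for name, X in (("biomarker", X_bio), ("mass", X_mass), ("combined", X_comb)):
        arr = X.to_numpy(dtype=float)
        this_lam = lam[name] if isinstance(lam, dict) else lam
        this_lam = (
            cv_lambda(arr, y, seed=seed) if this_lam == "cv" else float(this_lam)
        )
        model = fit_lasso_logistic(arr, y, this_lam, feature_names=list(X.columns))
        out[name] = roc(predict_prob(model, X), y)
    return out
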