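"""Logistic classification of texture feature vectors, with evaluation tools.

The model is the standard binary logistic regression: for feature vector
M_1..M_k the log-odds of malignancy are linear,

    log(pi / (1 - pi)) = alpha + sum_j beta_j * z_j,

with z_j the z-scored feature, and pi = 1 / (1 + exp(-a)) the inverse-logit.
Fitting maximizes the Bernoulli log-likelihood by Newton-Raphson with
step-halving, optionally with a small ridge penalty (lambda/2 * ||beta||^2,
intercept unpenalized) for stability on separable data.  Standardization
statistics are estimated on the training data only and stored with the model
so prediction is self-contained.

Evaluation: confusion counts with malignant = positive class, the derived
accuracy/precision/recall/F1 metrics, and deterministic stratified k-fold
cross-validation with pooled counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "ULRModel",
    "ConfusionCounts",
    "Metrics",
    "CVResult",
    "log_odds",
    "predict_prob",
    "fit",
    "classify",
    "confusion",
    "metrics",
    "stratified_folds",
    "cross_validate",
]


@dataclass
class ULRModel:
    """Fitted logistic model: intercept, coefficients and scaling metadata."""

    alpha: float
    betas: np.ndarray
    feature_names: list[str]
    standardize_means: np.ndarray
    standardize_sds: np.ndarray
    ridge_lambda: float = 0.0
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        self.standardize_means = np.asarray(self.standardize_means, dtype=float)
        self.standardize_sds = np.asarray(self.standardize_sds, dtype=float)
        k = len(self.feature_names)
        if not (self.betas.shape == self.standardize_means.shape
                == self.standardize_sds.shape == (k,)):
            raise ValueError("betas, names and standardization arrays must align")
        if np.any(self.standardize_sds <= 0):
            raise ValueError("standardization SDs must be positive")

    def _standardize(self, x: np.ndarray) -> np.ndarray:
        return (x - self.standardize_means) / self.standardize_sds


def _check_features(model: ULRModel, x, names=None) -> np.ndarray:
    if isinstance(x, dict):
        missing = [n for n in model.feature_names if n not in x]
        if missing:
            raise ValueError(f"feature(s) missing from input: {missing}")
        arr = np.array([x[n] for n in model.feature_names], dtype=float)
    else:
        arr = np.asarray(x, dtype=float)
        if names is not None and list(names) != model.feature_names:
            raise ValueError("feature names do not match the model")
    if arr.shape[-1] != len(model.feature_names):
        raise ValueError(
            f"expected {len(model.feature_names)} features, got {arr.shape[-1]}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite feature values")
    return arr


def log_odds(model: ULRModel, x, names=None) -> np.ndarray | float:
    """Linear predictor a = alpha + beta . z on standardized features."""
    arr = _check_features(model, x, names)
    a = model.alpha + model._standardize(arr) @ model.betas
    return float(a) if np.ndim(a) == 0 else a


def predict_prob(model: ULRModel, x, names=None) -> np.ndarray | float:
    """Malignancy probability pi = 1/(1 + e^-a); P(benign) = 1 - pi."""
    return expit(log_odds(model, x, names))


def classify(model: ULRModel, x, threshold: float = 0.5, names=None):
    """Label 1 (malignant) iff pi >= threshold; ties go to the positive class."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    p = predict_prob(model, x, names)
    return (np.asarray(p) >= threshold).astype(int) if np.ndim(p) else int(p >= threshold)


def _log_likelihood(a: np.ndarray, y: np.ndarray) -> float:
    # numerically stable: log(1+e^a) = max(a,0) + log1p(e^-|a|)
    return float(np.sum(y * a - (np.maximum(a, 0) + np.log1p(np.exp(-np.abs(a))))))


def fit(
    X,
    y,
    feature_names=None,
    ridge_lambda: float = 1e-6,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> ULRModel:
    """Maximum-likelihood logistic fit by Newton-Raphson.

    Features are z-scored internally (statistics stored on the model).  The
    ridge penalty (default 1e-6, intercept unpenalized) keeps the Hessian
    well-conditioned when the classes are linearly separable; at
    ``ridge_lambda=0`` a separable fit is flagged ``converged=False`` with a
    warning suggesting a positive ridge.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be n x k with one label per row")
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"need n > k+1 observations (n={n}, k={k})")
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError("labels must contain both classes 0 and 1")
    if ridge_lambda < 0:
        raise ValueError("ridge_lambda must be nonnegative")
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(k)]
    feature_names = list(feature_names)

    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    if np.any(sd <= 0):
        bad = [feature_names[j] for j in np.flatnonzero(sd <= 0)]
        raise ValueError(f"constant feature column(s): {bad}")
    Z = np.column_stack([np.ones(n), (X - mu) / sd])
    pen = np.full(k + 1, ridge_lambda)
    pen[0] = 0.0  # intercept unpenalized

    theta = np.zeros(k + 1)
    ll = _log_likelihood(Z @ theta, y) - 0.5 * float(pen @ theta**2)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        a = Z @ theta
        p = expit(a)
        grad = Z.T @ (y - p) - pen * theta
        w = np.maximum(p * (1 - p), 1e-12)
        hess = (Z * w[:, None]).T @ Z + np.diag(pen)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        # step-halving keeps the penalized log-likelihood non-decreasing
        scale = 1.0
        for _ in range(30):
            cand = theta + scale * step
            ll_new = _log_likelihood(Z @ cand, y) - 0.5 * float(pen @ cand**2)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        theta_new = theta + scale * step
        delta = np.max(np.abs(theta_new - theta))
        theta, ll = theta_new, max(ll, ll_new)
        if delta < tol:
            converged = True
            break

    if not converged and ridge_lambda == 0:
        warnings.warn(
            "logistic fit did not converge (possible perfect separation); "
            "refit with ridge_lambda > 0",
            RuntimeWarning,
            stacklevel=2,
        )
    return ULRModel(
        alpha=float(theta[0]),
        betas=theta[1:],
        feature_names=feature_names,
        standardize_means=mu,
        standardize_sds=sd,
        ridge_lambda=ridge_lambda,
        converged=converged,
        n_iter=it,
    )


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")
        if self.total == 0:
            raise ValueError("confusion counts are all zero")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )


def confusion(pred, truth) -> ConfusionCounts:
    """Confusion counts with positive class = 1 (malignant)."""
    pred = np.asarray(pred, dtype=int).ravel()
    truth = np.asarray(truth, dtype=int).ravel()
    if pred.size != truth.size or pred.size == 0:
        raise ValueError("pred and truth must have equal, positive length")
    for name, arr in (("pred", pred), ("truth", truth)):
        if not np.isin(arr, [0, 1]).all():
            raise ValueError(f"{name} labels must be binary")
    return ConfusionCounts(
        tp=int(np.sum((pred == 1) & (truth == 1))),
        tn=int(np.sum((pred == 0) & (truth == 0))),
        fp=int(np.sum((pred == 1) & (truth == 0))),
        fn=int(np.sum((pred == 0) & (truth == 1))),
    )


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    undefined: tuple[str, ...] = ()  # ratios whose denominator was zero


def metrics(c: ConfusionCounts) -> Metrics:
    """Accuracy (tp+tn)/n, precision, recall and F1 from confusion counts.

    A ratio with zero denominator is reported as 0 and listed in
    ``undefined`` rather than raising, so pooled cross-validation never
    aborts on a degenerate fold.
    """
    undefined: list[str] = []
    acc = (c.tp + c.tn) / c.total
    if c.tp + c.fp == 0:
        precision, _ = 0.0, undefined.append("precision")
    else:
        precision = c.tp / (c.tp + c.fp)
    if c.tp + c.fn == 0:
        recall, _ = 0.0, undefined.append("recall")
    else:
        recall = c.tp / (c.tp + c.fn)
    if precision + recall == 0:
        f1, _ = 0.0, undefined.append("f1")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return Metrics(acc, precision, recall, f1, tuple(undefined))


def stratified_folds(labels, k_folds: int, seed: int) -> list[np.ndarray]:
    """Deterministic stratified fold assignment; per-class sizes differ by <= 1.

    Each class's indices are shuffled with an RNG derived from ``seed`` and
    dealt round-robin to the folds.  Returns a list of index arrays.
    """
    labels = np.asarray(labels, dtype=int).ravel()
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k_folds)]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < k_folds:
            raise ValueError(
                f"class {cls} has {idx.size} members, fewer than {k_folds} folds"
            )
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            folds[i % k_folds].append(int(j))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


@dataclass
class CVResult:
    fold_counts: list[ConfusionCounts]
    fold_metrics: list[Metrics]
    pooled_counts: ConfusionCounts = field(init=False)
    pooled_metrics: Metrics = field(init=False)

    def __post_init__(self) -> None:
        pooled = self.fold_counts[0]
        for c in self.fold_counts[1:]:
            pooled = pooled + c
        self.pooled_counts = pooled
        self.pooled_metrics = metrics(pooled)


def cross_validate(
    X,
    y,
    feature_names=None,
    k_folds: int = 5,
    seed: int = 0,
    ridge_lambda: float = 1e-6,
    threshold: float = 0.5,
) -> CVResult:
    """Stratified k-fold CV of the logistic classifier with pooled counts."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int).ravel()
    folds = stratified_folds(y, k_folds, seed)
    fold_counts: list[ConfusionCounts] = []
    for held_out in folds:
        train = np.setdiff1d(np.arange(y.size), held_out)
        model = fit(X[train], y[train], feature_names, ridge_lambda=ridge_lambda)
        pred = classify(model, X[held_out], threshold=threshold)
        fold_counts.append(confusion(pred, y[held_out]))
    return CVResult(fold_counts, [metrics(c) for c in fold_counts])
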