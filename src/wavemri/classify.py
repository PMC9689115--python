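"""Regularized logistic regression (l2, l1, Elastic-Net) from first principles.

The binary objective, with labels y in {-1, +1}, is

    l2:      min_{w,c}  (1/2) w^T w          + C sum_i log(1 + exp(-y_i (x_i^T w + c)))
    l1:      min_{w,c}  ||w||_1              + C sum_i log(1 + exp(-y_i (x_i^T w + c)))
    elastic: min_{w,c}  (1-mix)/2 w^T w + mix ||w||_1 + C sum_i log(...)

The intercept c is never penalized.  C scales the data term, so *larger* C
means weaker regularization (liblinear convention).  The solver is proximal
gradient descent with backtracking line search: the l1 part is handled by
soft-thresholding, which produces exact zeros, and each accepted step is
required not to increase the objective, so the recorded objective history is
monotone non-increasing.

Multiclass uses one-vs-rest by default (one binary problem per class, the
stated objectives verbatim); a multinomial softmax variant with the same
penalties is available.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LogisticModel",
    "Prediction",
    "regularized_cost",
    "fit_logistic",
    "predict_class",
    "save_model",
    "load_model",
    "PENALTIES",
]

PENALTIES = ("l2", "l1", "elasticnet")


def _check_penalty(penalty: str, mix: float, C: float) -> None:
    if penalty not in PENALTIES:
        raise ValueError(f"penalty must be one of {PENALTIES}, got {penalty!r}")
    if not 0.0 <= mix <= 1.0:
        raise ValueError(f"mix must lie in [0, 1], got {mix}")
    if C <= 0:
        raise ValueError(f"C must be positive, got {C}")


def _penalty_split(penalty: str, mix: float) -> tuple[float, float]:
    """(smooth l2 coefficient, nonsmooth l1 coefficient) of the penalty."""
    if penalty == "l2":
        return 0.5, 0.0
    if penalty == "l1":
        return 0.0, 1.0
    return (1.0 - mix) / 2.0, mix


def _log_loss(margins: np.ndarray) -> float:
    """sum_i log(1 + exp(-m_i)), numerically stable."""
    return float(np.logaddexp(0.0, -margins).sum())


def regularized_cost(w: np.ndarray, c: float, X: np.ndarray, y: np.ndarray,
                     penalty: str = "l2", C: float = 1.0,
                     mix: float = 0.5) -> float:
    """Value of the selected binary objective at (w, c)."""
    w = np.atleast_1d(np.asarray(w, dtype=np.float64))
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64)
    if not np.all(np.isin(y, (-1.0, 1.0))):
        raise ValueError("labels must take values in {-1, +1}")
    _check_penalty(penalty, mix, C)
    l2c, l1c = _penalty_split(penalty, mix)
    margins = y * (X @ w + c)
    return l2c * float(w @ w) + l1c * float(np.abs(w).sum()) + C * _log_loss(margins)


def _soft_threshold(v: np.ndarray, thr: float) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - thr, 0.0)


def _prox_solve(grad_smooth, smooth_val, l1c, theta0, n_w, tol, max_iter):
    """Monotone proximal gradient on  smooth(theta) + l1c * ||theta[:n_w]||_1.

    ``theta`` packs the penalized weights first, then unpenalized intercepts.
    Returns (theta, objective_history, converged).
    """

    def full_val(th):
        return smooth_val(th) + l1c * float(np.abs(th[:n_w]).sum())

    theta = theta0.astype(np.float64).copy()
    step = 1.0
    F = full_val(theta)
    history = [F]
    converged = False
    for _ in range(max_iter):
        g = grad_smooth(theta)
        gs = smooth_val(theta)
        while True:
            cand = theta - step * g
            cand[:n_w] = _soft_threshold(cand[:n_w], step * l1c)
            delta = cand - theta
            # quadratic majorization of the smooth part at the current step
            if smooth_val(cand) <= gs + g @ delta + (delta @ delta) / (2 * step):
                break
            step /= 2.0
            if step < 1e-18:
                cand = theta
                break
        F_new = full_val(cand)
        if F_new > F:  # safeguard: never accept an increase
            F_new, cand = F, theta
        history.append(F_new)
        moved = not np.array_equal(cand, theta)
        theta = cand
        if abs(F - F_new) <= tol * max(1.0, abs(F_new)):
            F = F_new
            converged = True
            break
        F = F_new
        if moved:
            step *= 1.25
    return theta, np.array(history), converged


def _fit_binary(X, y, penalty, C, mix, tol, max_iter):
    n, d = X.shape
    l2c, l1c = _penalty_split(penalty, mix)

    def smooth_val(theta):
        w, c = theta[:d], theta[d]
        return l2c * float(w @ w) + C * _log_loss(y * (X @ w + c))

    def grad_smooth(theta):
        w, c = theta[:d], theta[d]
        m = y * (X @ w + c)
        # d/dm log(1+exp(-m)) = -sigmoid(-m)
        s = -1.0 / (1.0 + np.exp(m))
        coef = C * y * s
        gw = 2 * l2c * w + X.T @ coef
        gc = float(coef.sum())
        return np.concatenate([gw, [gc]])

    theta0 = np.zeros(d + 1)
    theta, hist, conv = _prox_solve(grad_smooth, smooth_val, l1c, theta0, d,
                                    tol, max_iter)
    return theta[:d], float(theta[d]), hist, conv


def _fit_multinomial(X, Y_onehot, penalty, C, mix, tol, max_iter):
    n, d = X.shape
    k = Y_onehot.shape[1]
    l2c, l1c = _penalty_split(penalty, mix)

    def unpack(theta):
        return theta[: k * d].reshape(k, d), theta[k * d:]

    def smooth_val(theta):
        W, b = unpack(theta)
        scores = X @ W.T + b
        lse = np.logaddexp.reduce(scores, axis=1)
        ll = float((lse - (scores * Y_onehot).sum(axis=1)).sum())
        return l2c * float((W ** 2).sum()) + C * ll

    def grad_smooth(theta):
        W, b = unpack(theta)
        scores = X @ W.T + b
        scores -= scores.max(axis=1, keepdims=True)
        P = np.exp(scores)
        P /= P.sum(axis=1, keepdims=True)
        R = P - Y_onehot
        gW = 2 * l2c * W + C * R.T @ X
        gb = C * R.sum(axis=0)
        return np.concatenate([gW.ravel(), gb])

    theta0 = np.zeros(k * d + k)
    theta, hist, conv = _prox_solve(grad_smooth, smooth_val, l1c, theta0,
                                    k * d, tol, max_iter)
    W, b = unpack(theta)
    return W, b, hist, conv


@dataclass
class LogisticModel:
    """Fitted multiclass logistic model (one weight row per class)."""

    weights: np.ndarray
    intercepts: np.ndarray
    penalty: str
    C: float
    mix: float
    scheme: str
    label_set: list
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    config_digest: str = ""
    converged: bool = True
    objective_histories: list = field(default_factory=list, repr=False)

    @property
    def n_classes(self) -> int:
        return len(self.label_set)


@dataclass(frozen=True)
class Prediction:
    probabilities: np.ndarray
    label: object


def fit_logistic(X: np.ndarray, labels: np.ndarray, penalty: str = "l2",
                 C: float = 1.0, mix: float = 0.5, scheme: str = "one-vs-rest",
                 tol: float = 1e-6, max_iter: int = 1000,
                 standardize: bool = True, config_digest: str = "",
                 seed: int | None = None) -> LogisticModel:
    """Fit a multiclass regularized logistic model.

    One-vs-rest (default) solves the binary objective above once per class
    with y = +1 for that class and -1 for the rest; ``multinomial`` solves a
    single softmax problem with the same penalty.  Features are standardized
    to zero mean / unit variance (constants kept on the model) unless
    ``standardize=False``.  The optimization is deterministic; ``seed`` is
    accepted for interface uniformity.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    labels = np.asarray(labels)
    classes = sorted(np.unique(labels).tolist())
    if len(classes) < 2:
        raise ValueError("at least 2 classes are required")
    _check_penalty(penalty, mix, C)
    if scheme not in ("one-vs-rest", "multinomial"):
        raise ValueError(f"unknown scheme {scheme!r}")

    if standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
    else:
        mean = np.zeros(X.shape[1])
        scale = np.ones(X.shape[1])
    Z = (X - mean) / scale

    histories = []
    if scheme == "one-vs-rest":
        W = np.zeros((len(classes), X.shape[1]))
        b = np.zeros(len(classes))
        conv_all = True
        for k, cls in enumerate(classes):
            y = np.where(labels == cls, 1.0, -1.0)
            W[k], b[k], hist, conv = _fit_binary(Z, y, penalty, C, mix,
                                                 tol, max_iter)
            histories.append(hist)
            conv_all &= conv
    else:
        Y = (labels[:, None] == np.asarray(classes)[None, :]).astype(np.float64)
        W, b, hist, conv_all = _fit_multinomial(Z, Y, penalty, C, mix,
                                                tol, max_iter)
        histories.append(hist)

    if not conv_all:
        warnings.warn(
            f"logistic solver did not reach tol={tol} within "
            f"max_iter={max_iter}; model carries converged=False",
            RuntimeWarning, stacklevel=2)
    return LogisticModel(
        weights=W, intercepts=b, penalty=penalty, C=float(C), mix=float(mix),
        scheme=scheme, label_set=classes, feature_mean=mean,
        feature_scale=scale, config_digest=config_digest,
        converged=bool(conv_all), objective_histories=histories)


def predict_class(model: LogisticModel, X: np.ndarray,
                  config_digest: str | None = None) -> list[Prediction]:
    """Per-row class probabilities and argmax label.

    One-vs-rest scores are per-class sigmoids normalized to sum to 1;
    multinomial uses the softmax.  Ties resolve to the earliest label in
    ``label_set``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != model.weights.shape[1]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model "
            f"dimension {model.weights.shape[1]}")
    if config_digest and model.config_digest and config_digest != model.config_digest:
        raise ValueError(
            "feature configuration digest does not match the one the model "
            "was trained with; refusing to predict")
    Z = (X - model.feature_mean) / model.feature_scale
    scores = Z @ model.weights.T + model.intercepts
    if model.scheme == "one-vs-rest":
        probs = 1.0 / (1.0 + np.exp(-scores))
        probs /= probs.sum(axis=1, keepdims=True)
    else:
        scores -= scores.max(axis=1, keepdims=True)
        probs = np.exp(scores)
        probs /= probs.sum(axis=1, keepdims=True)
    out = []
    for row in probs:
        out.append(Prediction(probabilities=row,
                              label=model.label_set[int(np.argmax(row))]))
    return out


def save_model(model: LogisticModel, path) -> None:
    """Serialize a model (weights, config, standardization, digest) to JSON."""
    payload = {
        "weights": model.weights.tolist(),
        "intercepts": model.intercepts.tolist(),
        "penalty": model.penalty,
        "C": model.C,
        "mix": model.mix,
        "scheme": model.scheme,
        "label_set": [str(x) for x in model.label_set],
        "feature_mean": model.feature_mean.tolist(),
        "feature_scale": model.feature_scale.tolist(),
        "config_digest": model.config_digest,
        "converged": model.converged,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def load_model(path) -> LogisticModel:
    with open(path) as fh:
        p = json.load(fh)
    return LogisticModel(
        weights=np.asarray(p["weights"], dtype=np.float64),
        intercepts=np.asarray(p["intercepts"], dtype=np.float64),
        penalty=p["penalty"], C=p["C"], mix=p["mix"], scheme=p["scheme"],
        label_set=p["label_set"],
        feature_mean=np.asarray(p["feature_mean"], dtype=np.float64),
        feature_scale=np.asarray(p["feature_scale"], dtype=np.float64),
        config_digest=p.get("config_digest", ""),
        converged=p.get("converged", True))
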