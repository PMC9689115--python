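"""Linear discriminant analysis: scatter matrices and the generalized eigenproblem.

For c classes with class means m_i (V_i samples each) and global mean m:

    VAR_B = sum_i V_i (m_i - m)(m_i - m)^T          (between-class scatter)
    VAR_W = sum_i sum_{x in C_i} (x - m_i)(x - m_i)^T  (within-class scatter)

The discriminant matrix D_o stacks the top-t generalized eigenvectors of
VAR_B d = w VAR_W d, which maximize the Fisher ratio d^T VAR_B d / d^T VAR_W d.
Since rank(VAR_B) <= c - 1, at most c - 1 directions are informative.  In the
features >> samples regime VAR_W is singular; a ridge term (VAR_W + ridge I)
keeps the eigenproblem well posed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = [
    "LabeledFeatures",
    "ScatterPair",
    "LdaProjection",
    "compute_scatter",
    "default_ridge",
    "fit_lda_projection",
    "project_features",
]


@dataclass
class LabeledFeatures:
    """A feature matrix (one row per image) with per-row class labels."""

    matrix: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.matrix.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.matrix.shape[0] != self.labels.shape[0]:
            raise ValueError("row count must equal label count")

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    @property
    def c(self) -> int:
        return len(self.classes)

    @property
    def r(self) -> int:
        return self.matrix.shape[1]


@dataclass
class ScatterPair:
    VAR_W: np.ndarray
    VAR_B: np.ndarray
    class_means: dict
    global_mean: np.ndarray
    class_weights: dict

    @property
    def c(self) -> int:
        return len(self.class_means)


@dataclass
class LdaProjection:
    """Discriminant matrix D_o (t x r, unit-norm rows) with eigenvalues."""

    D_o: np.ndarray
    eigenvalues: np.ndarray
    ridge: float

    @property
    def t(self) -> int:
        return self.D_o.shape[0]

    @property
    def r(self) -> int:
        return self.D_o.shape[1]


def compute_scatter(data: LabeledFeatures) -> ScatterPair:
    """Between- and within-class scatter matrices of labeled features."""
    if data.c < 2:
        raise ValueError("at least 2 classes are required for LDA scatter")
    X = data.matrix
    global_mean = X.mean(axis=0)
    r = data.r
    VAR_B = np.zeros((r, r))
    VAR_W = np.zeros((r, r))
    class_means, class_weights = {}, {}
    for cls in data.classes:
        Xi = X[data.labels == cls]
        Vi = Xi.shape[0]
        mi = Xi.mean(axis=0)
        class_means[cls] = mi
        class_weights[cls] = Vi
        db = mi - global_mean
        VAR_B += Vi * np.outer(db, db)
        dw = Xi - mi
        VAR_W += dw.T @ dw
    # symmetrize against float drift
    VAR_B = (VAR_B + VAR_B.T) / 2
    VAR_W = (VAR_W + VAR_W.T) / 2
    return ScatterPair(VAR_W=VAR_W, VAR_B=VAR_B, class_means=class_means,
                       global_mean=global_mean, class_weights=class_weights)


def default_ridge(VAR_W: np.ndarray, eps: float = 1e-4) -> float:
    """Default ridge: eps * trace(VAR_W) / r (scale-aware)."""
    r = VAR_W.shape[0]
    return float(eps * np.trace(VAR_W) / r)


def fit_lda_projection(scatter: ScatterPair, t: int,
                       ridge: float = 0.0) -> LdaProjection:
    """Top-t generalized eigenvectors of (VAR_B, VAR_W + ridge I).

    Rows of D_o are unit-norm, ordered by descending eigenvalue; the first
    component of magnitude > 1e-12 of each row is made positive for
    reproducibility.
    """
    c = scatter.c
    if not 1 <= t <= c - 1:
        raise ValueError(
            f"t must satisfy 1 <= t <= c - 1 = {c - 1} (at most c - 1 "
            f"informative discriminant directions exist), got t={t}")
    W_reg = scatter.VAR_W + ridge * np.eye(scatter.VAR_W.shape[0])
    try:
        np.linalg.cholesky(W_reg)
    except np.linalg.LinAlgError:
        raise ValueError(
            "within-class scatter is singular; pass ridge > 0 "
            "(e.g. default_ridge(VAR_W))") from None
    w, v = scipy.linalg.eigh(scatter.VAR_B, W_reg)
    order = np.argsort(w, kind="stable")[::-1][:t]
    eigvals = w[order]
    D = v[:, order].T
    D = D / np.linalg.norm(D, axis=1, keepdims=True)
    for row in D:
        nz = np.flatnonzero(np.abs(row) > 1e-12)
        if nz.size and row[nz[0]] < 0:
            row *= -1.0
    return LdaProjection(D_o=D, eigenvalues=eigvals, ridge=float(ridge))


def project_features(data: LabeledFeatures, proj: LdaProjection) -> LabeledFeatures:
    """Map rows into the t-dimensional discriminant space; labels preserved."""
    if data.r != proj.r:
        raise ValueError(
            f"feature dimension {data.r} does not match projection "
            f"dimension {proj.r}")
    return LabeledFeatures(matrix=data.matrix @ proj.D_o.T, labels=data.labels)
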