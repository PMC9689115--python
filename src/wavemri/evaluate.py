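"""Cross-validated evaluation: folds, confusion matrices, metrics, driver.

The evaluation protocol is stratified n-fold cross-validation: every image
is used for testing exactly once and for training in the remaining folds.
All fitted state (LDA projection, feature standardization, classifier
weights) is estimated on training folds only; preprocessing and feature
extraction are per-image deterministic maps with no fitted state, so they
cannot leak test information.

Per-class one-vs-rest counts collapse the confusion matrix to
(Tp, Tn, Fp, Fn), from which two metric variants are computed:

* ``paper``    — sensitivity = Tp/(Tp+Fp), accuracy = (Tp+Tn)/total,
                 specificity = Tn/(Tn+Fp)   (as-reported convention; note this
                 sensitivity formula is conventionally called precision)
* ``standard`` — sensitivity = Tp/(Tp+Fn), same accuracy and specificity.

The headline figure is the average recognition rate: the mean of the
diagonal of the row-normalized (percentage) confusion matrix.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as wio
from .classify import fit_logistic, predict_class
from .config import PipelineConfig
from .features import feature_matrix
from .lda import (LabeledFeatures, compute_scatter, default_ridge,
                  fit_lda_projection, project_features)
from .preprocess import GrayImage, equalize_global, resize_image

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "stratified_folds",
    "cross_validate_features",
    "run_cross_validation",
    "binary_counts_for_class",
    "compute_metrics",
    "average_recognition_rate",
    "run_pipeline",
]


@dataclass
class ConfusionMatrix:
    """c x c counts indexed (true class, predicted class)."""

    counts: np.ndarray
    class_order: list

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        c = len(self.class_order)
        if self.counts.shape != (c, c):
            raise ValueError("counts must be square with one row per class")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_labels(cls, true_labels, predicted_labels, class_order=None):
        true_labels = list(true_labels)
        predicted_labels = list(predicted_labels)
        if class_order is None:
            class_order = sorted(set(true_labels) | set(predicted_labels))
        index = {lbl: i for i, lbl in enumerate(class_order)}
        counts = np.zeros((len(class_order), len(class_order)), dtype=np.int64)
        for t, p in zip(true_labels, predicted_labels, strict=True):
            counts[index[t], index[p]] += 1
        return cls(counts=counts, class_order=list(class_order))

    def row_normalized_percent(self) -> np.ndarray:
        """Rows as percentages (each row sums to 100 for non-empty rows)."""
        sums = self.counts.sum(axis=1, keepdims=True).astype(np.float64)
        sums[sums == 0] = np.nan
        return self.counts / sums * 100.0


def binary_counts_for_class(cm: ConfusionMatrix, k) -> tuple[int, int, int, int]:
    """One-vs-rest collapse of the confusion matrix for class ``k``.

    Returns (Tp, Tn, Fp, Fn): Tp = cm[k, k], Fn = rest of row k,
    Fp = rest of column k, Tn = everything else.
    """
    if k not in cm.class_order:
        raise ValueError(f"unknown class {k!r}")
    i = cm.class_order.index(k)
    tp = int(cm.counts[i, i])
    fn = int(cm.counts[i, :].sum()) - tp
    fp = int(cm.counts[:, i].sum()) - tp
    tn = cm.total - tp - fp - fn
    return tp, tn, fp, fn


def compute_metrics(tp: int, tn: int, fp: int, fn: int,
                    variant: str = "paper") -> tuple[float, float, float]:
    """(sensitivity, accuracy, specificity) from one-vs-rest counts.

    A zero denominator yields NaN (undefined-metric marker), not an error.
    """
    if variant not in ("paper", "standard"):
        raise ValueError(f"variant must be 'paper' or 'standard', got {variant!r}")
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("counts must be non-negative")

    def ratio(num, den):
        return num / den if den > 0 else math.nan

    sens_den = tp + fp if variant == "paper" else tp + fn
    sensitivity = ratio(tp, sens_den)
    accuracy = ratio(tp + tn, tp + fp + tn + fn)
    specificity = ratio(tn, tn + fp)
    return sensitivity, accuracy, specificity


def average_recognition_rate(cm: ConfusionMatrix) -> float:
    """Mean of the diagonal of the row-normalized percentage matrix."""
    return float(np.nanmean(np.diag(cm.row_normalized_percent())))


@dataclass
class MetricsReport:
    """Per-class and macro-averaged metrics of one confusion matrix."""

    variant: str
    per_class: dict = field(default_factory=dict)
    macro_sensitivity: float = math.nan
    macro_accuracy: float = math.nan
    macro_specificity: float = math.nan
    average_recognition_rate_pct: float = math.nan

    @classmethod
    def from_confusion(cls, cm: ConfusionMatrix, variant: str = "paper"):
        per_class = {}
        sens, acc, spec = [], [], []
        for k in cm.class_order:
            tp, tn, fp, fn = binary_counts_for_class(cm, k)
            s, a, p = compute_metrics(tp, tn, fp, fn, variant)
            per_class[k] = {"Tp": tp, "Tn": tn, "Fp": fp, "Fn": fn,
                            "sensitivity": s, "accuracy": a, "specificity": p}
            sens.append(s)
            acc.append(a)
            spec.append(p)
        return cls(
            variant=variant, per_class=per_class,
            macro_sensitivity=float(np.nanmean(sens)),
            macro_accuracy=float(np.nanmean(acc)),
            macro_specificity=float(np.nanmean(spec)),
            average_recognition_rate_pct=average_recognition_rate(cm))


def stratified_folds(labels, n_folds: int, seed: int = 0) -> np.ndarray:
    """Per-sample fold indices; each class is split as evenly as possible."""
    labels = np.asarray(labels)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rng = np.random.default_rng(seed)
    folds = np.full(len(labels), -1, dtype=np.int64)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < n_folds:
            raise ValueError(
                f"class {cls!r} has {len(idx)} samples, fewer than "
                f"n_folds={n_folds}; use a smaller n_folds")
        idx = rng.permutation(idx)
        folds[idx] = np.arange(len(idx)) % n_folds
    return folds


def cross_validate_features(X: np.ndarray, labels, n_folds: int, seed: int,
                            fit_fn, predict_fn,
                            folds: np.ndarray | None = None) -> ConfusionMatrix:
    """Generic stratified CV over a precomputed feature matrix.

    ``fit_fn(X_train, y_train) -> state`` and
    ``predict_fn(state, X_test) -> labels``; every sample is predicted
    exactly once and accumulated into one confusion matrix.  A precomputed
    per-sample fold assignment may be supplied via ``folds``.
    """
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels)
    class_order = sorted(np.unique(labels).tolist())
    if folds is None:
        folds = stratified_folds(labels, n_folds, seed)
    folds = np.asarray(folds)
    counts = np.zeros((len(class_order), len(class_order)), dtype=np.int64)
    index = {lbl: i for i, lbl in enumerate(class_order)}
    for f in range(n_folds):
        test = folds == f
        state = fit_fn(X[~test], labels[~test])
        predicted = predict_fn(state, X[test])
        for t, p in zip(labels[test], predicted, strict=True):
            counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, class_order=class_order)


def _preprocess_one(img: GrayImage, cfg: PipelineConfig) -> GrayImage:
    if cfg.resize_h > 0 and cfg.resize_w > 0:
        img = resize_image(img, cfg.resize_h, cfg.resize_w)
    if cfg.equalize == "on":
        img, _ = equalize_global(img)
    return img


def extract_features(images: list[GrayImage],
                     cfg: PipelineConfig) -> tuple[np.ndarray, str]:
    """Preprocess and featurize a list of images under one configuration."""
    processed = [_preprocess_one(im, cfg) for im in images]
    return feature_matrix(processed, wavelet=cfg.wavelet, levels=cfg.levels,
                          mode=cfg.boundary_mode, feature_mode=cfg.feature_mode)


def _make_fold_fitter(cfg: PipelineConfig, digest: str):
    def fit_fn(X_train, y_train):
        data = LabeledFeatures(matrix=X_train, labels=y_train)
        scatter = compute_scatter(data)
        t = min(cfg.lda_dims, data.c - 1)
        ridge = default_ridge(scatter.VAR_W, cfg.lda_ridge)
        proj = fit_lda_projection(scatter, t=t, ridge=ridge)
        reduced = project_features(data, proj)
        model = fit_logistic(reduced.matrix, reduced.labels,
                             penalty=cfg.penalty, C=cfg.C, mix=cfg.mix,
                             scheme=cfg.scheme, tol=cfg.tol,
                             max_iter=cfg.max_iter, config_digest=digest)
        return proj, model

    def predict_fn(state, X_test):
        proj, model = state
        reduced = X_test @ proj.D_o.T
        return [p.label for p in predict_class(model, reduced)]

    return fit_fn, predict_fn


def run_cross_validation(images: list[GrayImage], labels,
                         cfg: PipelineConfig | None = None,
                         n_folds: int | None = None,
                         seed: int | None = None) -> ConfusionMatrix:
    """End-to-end stratified CV of the full pipeline on in-memory images."""
    cfg = cfg or PipelineConfig()
    n_folds = cfg.n_folds if n_folds is None else n_folds
    seed = cfg.seed if seed is None else seed
    X, digest = extract_features(images, cfg)
    fit_fn, predict_fn = _make_fold_fitter(cfg, digest)
    return cross_validate_features(X, labels, n_folds, seed, fit_fn, predict_fn)


def run_pipeline(cfg: PipelineConfig, dataset_path, output_dir
                 ) -> tuple[MetricsReport, ConfusionMatrix]:
    """Load a dataset directory, cross-validate, and write report files.

    Writes: confusion_counts.csv, confusion_percent.csv (row-normalized,
    Table-style percentages), metrics.json (both variants plus the average
    recognition rate), and run_log.txt echoing every config value.  Reruns
    with the same config and seed produce byte-identical files.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    images, labels = wio.load_dataset(dataset_path)
    cm = run_cross_validation(images, labels, cfg)

    counts_df = pd.DataFrame(cm.counts, index=cm.class_order,
                             columns=cm.class_order)
    counts_df.to_csv(out / "confusion_counts.csv")
    pct_df = pd.DataFrame(cm.row_normalized_percent(), index=cm.class_order,
                          columns=cm.class_order)
    pct_df.to_csv(out / "confusion_percent.csv", float_format="%.4f")

    reports = {v: MetricsReport.from_confusion(cm, v)
               for v in ("paper", "standard")}
    payload = {
        "average_recognition_rate_pct":
            reports["paper"].average_recognition_rate_pct,
        "n_images": cm.total,
        "n_classes": len(cm.class_order),
        "variants": {
            v: {
                "macro_sensitivity": r.macro_sensitivity,
                "macro_accuracy": r.macro_accuracy,
                "macro_specificity": r.macro_specificity,
                "per_class": r.per_class,
            } for v, r in reports.items()
        },
    }
    with open(out / "metrics.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, allow_nan=True)

    with open(out / "run_log.txt", "w") as fh:
        fh.write("wavemri cross-validation run\n")
        for key, value in cfg.to_dict().items():
            fh.write(f"{key} = {value}\n")
    return reports["paper"], cm
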