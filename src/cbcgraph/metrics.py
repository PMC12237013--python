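"""Evaluation metrics for imbalanced binary classification.

AUROC is the primary metric: it is threshold independent and equals the
probability that a uniformly random positive receives a higher score than
a uniformly random negative, with ties counted one half (the
Mann-Whitney rank formulation). F1-macro and the Matthews correlation
coefficient (MCC) are computed at a configurable probability threshold
(0.5 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn import metrics as _skm

__all__ = ["auroc", "f1_macro", "mcc", "MetricReport", "evaluate",
           "add_noise_features"]


def _check_two_classes(labels: np.ndarray) -> None:
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present in labels")


def auroc(labels, scores) -> float:
    """Area under the ROC curve (rank/Mann-Whitney formulation)."""
    labels = np.asarray(labels)
    _check_two_classes(labels)
    return float(_skm.roc_auc_score(labels, np.asarray(scores, dtype=float)))


def f1_macro(labels, predictions) -> float:
    """Unweighted mean of the per-class F1 scores.

    A class with neither predictions nor members contributes F1 = 0.
    """
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    _check_two_classes(labels)
    return float(_skm.f1_score(labels, predictions, average="macro",
                               zero_division=0))


def mcc(labels, predictions) -> float:
    """Matthews correlation coefficient; 0 when any confusion-matrix
    marginal is 0."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    _check_two_classes(labels)
    return float(_skm.matthews_corrcoef(labels, predictions))


@dataclass(frozen=True)
class MetricReport:
    auroc: float
    f1_macro: float
    mcc: float
    threshold: float = 0.5

    def as_dict(self) -> dict:
        return {"auroc": self.auroc, "f1_macro": self.f1_macro,
                "mcc": self.mcc, "threshold": self.threshold}


def evaluate(labels, scores, threshold: float = 0.5) -> MetricReport:
    """AUROC from scores plus F1-macro/MCC at the given probability
    threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    scores = np.asarray(scores, dtype=float)
    preds = (scores >= threshold).astype(np.int64)
    return MetricReport(
        auroc=auroc(labels, scores),
        f1_macro=f1_macro(labels, preds),
        mcc=mcc(labels, preds),
        threshold=threshold)


def add_noise_features(X, n_noise: int, seed: int = 0) -> np.ndarray:
    """Append ``n_noise`` i.i.d. uniform-[0, 1) columns to ``X``.

    Used for the noise-robustness benchmark; the original columns are
    untouched and the noise is seeded.
    """
    if n_noise < 0:
        raise ValueError("n_noise must be >= 0")
    X = np.asarray(X, dtype=float)
    if n_noise == 0:
        return X.copy()
    rng = np.random.default_rng(seed)
    return np.concatenate([X, rng.random((X.shape[0], n_noise))], axis=1)
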