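"""ROC curves, AUC and misclassification error.

AUC is the probability that a random positive sample receives a higher
score than a random negative one, ties counted one half (the Mann-Whitney
identity); the curve itself comes from a threshold sweep over the distinct
scores, and its trapezoidal area equals that probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_curve


@dataclass
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """ROC curve and AUC for +/-1 labels scored by a real decision value."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thresholds = roc_curve(labels, scores, pos_label=1)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def multiclass_auc(
    proba: np.ndarray, labels: np.ndarray, classes: list[str]
) -> float:
    """Macro-averaged one-vs-rest AUC over the probability columns.

    Each class's own probability column is the score for a binary
    class-vs-rest problem; classes absent from ``labels`` are skipped with
    a warning.
    """
    proba = np.asarray(proba, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if proba.shape != (labels.size, len(classes)):
        raise ValueError("proba must be n x c with c = len(classes)")
    if np.any(np.abs(proba.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("probability rows must sum to 1")
    aucs = []
    for k, cls in enumerate(classes):
        mask = labels == cls
        if not mask.any() or mask.all():
            warnings.warn(
                f"class {cls!r} absent from one side; skipped in macro AUC",
                stacklevel=2,
            )
            continue
        y = np.where(mask, 1.0, -1.0)
        aucs.append(roc_auc(proba[:, k], y).auc)
    if not aucs:
        raise ValueError("no class had both members and non-members")
    return float(np.mean(aucs))


def predictive_error(predicted: np.ndarray, actual: np.ndarray) -> float:
    """Fraction of mismatched labels, in [0, 1]."""
    predicted = np.asarray(predicted)
    actual = np.asarray(actual)
    if predicted.shape != actual.shape:
        raise ValueError("predicted and actual differ in length")
    return float(np.mean(predicted != actual))


def write_roc_tsv(result: ROCResult, path: str | Path) -> None:
    """Export ROC points as TSV (threshold, fpr, tpr) for plotting."""
    lines = ["threshold\tfpr\ttpr"]
    for t, f, s in zip(result.thresholds, result.fpr, result.tpr):
        lines.append(f"{float(t)!r}\t{float(f)!r}\t{float(s)!r}")
    Path(path).write_text("\n".join(lines) + "\n")
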