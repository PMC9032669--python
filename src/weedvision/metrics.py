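"""Classification performance metrics and the stratified data split.

Performance is reported per class via one-vs-rest reductions of the 3×3
confusion matrix (rows = true class, columns = predicted), in the class
order (Crop, NLW, BLW):

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 · precision · recall / (precision + recall)

Macro averages are the unweighted per-class means; overall accuracy
(trace / total) is also reported since the dataset is class-balanced and
the two coincide in expectation.  Divisions by zero yield 0 with a flag
rather than NaN, so degenerate runs still produce a report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CLASSES",
    "confusion_matrix",
    "ClassMetrics",
    "metrics_from_confusion",
    "classification_report",
    "stratified_split",
]

#: Canonical class order: corn crop, narrow-leaf weeds, broadleaf weeds.
CLASSES = ("Crop", "NLW", "BLW")


def confusion_matrix(y_true, y_pred, classes=CLASSES) -> pd.DataFrame:
    """Counts[i, j] = number of samples with true class i predicted as j."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred differ in length")
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise ValueError(f"label outside class list {classes}: ({t!r}, {p!r})")
        cm[index[t], index[p]] += 1
    return pd.DataFrame(cm, index=list(classes), columns=list(classes))


@dataclass(frozen=True)
class ClassMetrics:
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    zero_division: bool = False


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def metrics_from_confusion(cm: pd.DataFrame, cls: str) -> ClassMetrics:
    """One-vs-rest TP/TN/FP/FN and the four metrics for one class."""
    counts = np.asarray(cm)
    if counts.sum() == 0:
        raise ValueError("empty confusion matrix")
    i = list(cm.index).index(cls)
    tp = int(counts[i, i])
    fn = int(counts[i].sum() - tp)
    fp = int(counts[:, i].sum() - tp)
    tn = int(counts.sum() - tp - fn - fp)
    accuracy = (tp + tn) / (tp + tn + fp + fn)
    precision, z1 = _safe_div(tp, tp + fp)
    recall, z2 = _safe_div(tp, tp + fn)
    f1, z3 = _safe_div(2 * precision * recall, precision + recall)
    return ClassMetrics(
        tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=accuracy, precision=precision, recall=recall, f1=f1,
        zero_division=z1 or z2 or z3,
    )


def classification_report(cm: pd.DataFrame) -> dict:
    """Per-class metrics, macro averages, and overall (trace/total) accuracy."""
    per_class = {cls: metrics_from_confusion(cm, cls) for cls in cm.index}
    macro = {
        name: float(np.mean([getattr(m, name) for m in per_class.values()]))
        for name in ("accuracy", "precision", "recall", "f1")
    }
    counts = np.asarray(cm)
    return {
        "per_class": per_class,
        "macro": macro,
        "overall_accuracy": float(np.trace(counts) / counts.sum()),
        "n_samples": int(counts.sum()),
    }


def stratified_split(
    labels, fractions=(0.7, 0.2, 0.1), seed: int = 0
) -> tuple[np.ndarray, ...]:
    """Index split honouring per-class proportions (largest-remainder rounding).

    Returns index arrays, one per fraction (train/validation/test for the
    default 70/20/10).  Within each class, items are shuffled by ``seed``
    and dealt out so subset sizes per class follow the fractions with
    largest-remainder rounding; the split is disjoint, exhaustive and
    reproducible.
    """
    fractions = tuple(float(f) for f in fractions)
    if any(f < 0 for f in fractions) or not np.isclose(sum(fractions), 1.0):
        raise ValueError(f"fractions must be non-negative and sum to 1, got {fractions}")
    labels = np.asarray(list(labels))
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[] for _ in fractions]
    for cls in pd.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        sizes = _largest_remainder(len(idx), fractions)
        start = 0
        for part, size in zip(parts, sizes):
            part.extend(idx[start : start + size].tolist())
            start += size
    return tuple(np.sort(np.asarray(p, dtype=np.int64)) for p in parts)


def _largest_remainder(n: int, fractions: tuple[float, ...]) -> list[int]:
    quotas = [n * f for f in fractions]
    sizes = [int(np.floor(q)) for q in quotas]
    remainder = n - sum(sizes)
    order = sorted(
        range(len(fractions)), key=lambda k: (quotas[k] - sizes[k]), reverse=True
    )
    for k in order[:remainder]:
        sizes[k] += 1
    return sizes
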