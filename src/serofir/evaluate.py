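"""Classification merits from pooled test predictions.

Test predictions of all cross-validation repeats are pooled into one
confusion matrix (true classes in rows, predicted in columns, fixed class
order) from which one-vs-rest per-class counts and rates are derived:
sensitivity (recall, TP/(TP+FN)), specificity (TN/(TN+FP)) and positive
predictive value (precision, TP/(TP+FP)), plus overall accuracy
(trace/total).  Zero-denominator rates are reported as explicit NaN
("undefined") markers, never silently as 0.  The confusion structure can be
exported as a chord-diagram edge list (source = true class, target =
predicted class, weight = count).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ConfusionMatrix", "pool_predictions", "class_metrics", "chord_export"]


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts matrix with its class order (rows true, columns predicted)."""

    classes: tuple
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if counts.shape != (k, k):
            raise EvaluationError(f"counts must be {k}x{k}, got {counts.shape}")
        if np.any(counts < 0):
            raise EvaluationError("confusion counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes),
                            columns=list(self.classes))


def pool_predictions(per_repeat, classes) -> ConfusionMatrix:
    """Sum (true, predicted) label pairs of every repeat into one matrix.

    ``per_repeat`` is an iterable of (true_labels, predicted_labels) pairs;
    labels must all belong to ``classes``.
    """
    classes = tuple(classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    n_pairs = 0
    for truth, pred in per_repeat:
        truth, pred = np.asarray(truth), np.asarray(pred)
        if truth.shape != pred.shape:
            raise EvaluationError("true/predicted length mismatch in a repeat")
        for t, p in zip(truth, pred):
            if t not in index or p not in index:
                bad = t if t not in index else p
                raise EvaluationError(f"label {bad!r} outside the class list {classes}")
            counts[index[t], index[p]] += 1
            n_pairs += 1
    if n_pairs == 0:
        raise EvaluationError("no predictions to pool")
    return ConfusionMatrix(classes=classes, counts=counts)


def class_metrics(cm: ConfusionMatrix) -> pd.DataFrame:
    """One-vs-rest TP/TN/FP/FN and rates per class, plus overall accuracy.

    Returns a DataFrame indexed by class with columns TP, TN, FP, FN,
    sensitivity, specificity, ppv, and an ``accuracy`` value repeated per
    row for convenience; undefined rates (zero denominators) are NaN.
    """
    if cm.total == 0:
        raise EvaluationError("empty confusion matrix")
    C = cm.counts
    total = cm.total
    rows = []
    for i, cls in enumerate(cm.classes):
        tp = int(C[i, i])
        fn = int(C[i].sum() - tp)
        fp = int(C[:, i].sum() - tp)
        tn = total - tp - fn - fp

        def rate(num: int, den: int) -> float:
            return num / den if den > 0 else float("nan")

        rows.append(
            {
                "class": cls, "TP": tp, "TN": tn, "FP": fp, "FN": fn,
                "sensitivity": rate(tp, tp + fn),
                "specificity": rate(tn, tn + fp),
                "ppv": rate(tp, tp + fp),
            }
        )
    out = pd.DataFrame(rows).set_index("class")
    out["accuracy"] = np.trace(C) / total
    return out


def chord_export(cm: ConfusionMatrix) -> pd.DataFrame:
    """Edge list of all nonzero cells, self-edges included.

    Columns: source (true class), target (predicted class), weight (count).
    """
    rows = [
        {"source": t, "target": p, "weight": int(cm.counts[i, j])}
        for i, t in enumerate(cm.classes)
        for j, p in enumerate(cm.classes)
        if cm.counts[i, j] > 0
    ]
    return pd.DataFrame(rows, columns=["source", "target", "weight"])
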