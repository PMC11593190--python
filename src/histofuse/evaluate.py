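"""Confusion matrices, one-vs-rest per-class counts and derived metrics.

For a K-class problem the confusion matrix C has rows indexed by true
class and columns by predicted class.  Treating class k as positive gives
the one-vs-rest counts

    TP = C[k,k],  FN = row_k - TP,  FP = col_k - TP,  TN = total - TP - FN - FP

from which precision = TP/(TP+FP), recall = TP/(TP+FN),
F1 = 2PR/(P+R) and the per-class (one-vs-rest) accuracy
(TP+TN)/total follow.  Ratios with a zero denominator are defined as 0.
The multiclass headline accuracy is trace/total.

Display rounding is 4 decimals, round-half-even; raw values are retained
in machine-readable output.  The canonical per-class display order is
(LACA, benign, LSCC).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imageio_preproc import CLASS_CODES, CLASS_NAMES

#: Per-class display order used by the confusion-matrix figures/reports.
DISPLAY_ORDER: tuple[str, ...] = ("LACA", "benign", "LSCC")
DISPLAY_CODES: tuple[int, ...] = tuple(CLASS_CODES[n] for n in DISPLAY_ORDER)


@dataclass
class ConfusionMatrix:
    """K x K counts (rows true, columns predicted) with their label order."""

    counts: np.ndarray
    labels: tuple

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("confusion matrix must be square")
        if c.min() < 0:
            raise ValueError("confusion counts must be non-negative")
        if c.shape[0] != len(self.labels):
            raise ValueError("label order must match matrix size")
        self.counts = c
        self.labels = tuple(self.labels)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels),
                            columns=list(self.labels))


@dataclass
class ClassCounts:
    """One-vs-rest TP/TN/FP/FN for a single class."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(y_true, y_pred, labels=None) -> ConfusionMatrix:
    """Count confusion-matrix entries for the given label order.

    When ``labels`` is omitted and the codes are the canonical 3-class
    vocabulary, the display order (LACA, benign, LSCC) i.e. codes (0, 2, 1)
    is used; otherwise labels are the sorted distinct codes.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("cannot build a confusion matrix from empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    present = set(np.unique(y_true)) | set(np.unique(y_pred))
    if labels is None:
        if present <= set(DISPLAY_CODES):
            labels = DISPLAY_CODES
        else:
            labels = tuple(sorted(present))
    else:
        labels = tuple(labels)
        unknown = present - set(labels)
        if unknown:
            raise ValueError(f"codes {sorted(unknown)} not in label order {labels}")
    index = {lab: i for i, lab in enumerate(labels)}
    K = len(labels)
    counts = np.zeros((K, K), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, labels=labels)


def class_counts(cm: ConfusionMatrix, k: int) -> ClassCounts:
    """One-vs-rest counts for the class at position k of the matrix order."""
    K = cm.counts.shape[0]
    if not 0 <= k < K:
        raise ValueError(f"class index {k} out of range for K={K}")
    tp = int(cm.counts[k, k])
    fn = int(cm.counts[k].sum()) - tp
    fp = int(cm.counts[:, k].sum()) - tp
    tn = cm.total - tp - fn - fp
    return ClassCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    return _ratio(2.0 * precision * recall, precision + recall)


def metrics_from_counts(c: ClassCounts) -> dict[str, float]:
    """Precision, recall, F1 and one-vs-rest accuracy from the counts."""
    precision = _ratio(c.tp, c.tp + c.fp)
    recall = _ratio(c.tp, c.tp + c.fn)
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1_score(precision, recall),
        "accuracy": _ratio(c.tp + c.tn, c.total),
    }


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Multiclass accuracy: trace / total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.total


def round4(x: float) -> float:
    """Display rounding: 4 decimals, round-half-even."""
    return round(float(x), 4)


def metrics_report(cm: ConfusionMatrix) -> pd.DataFrame:
    """Per-class metrics table (raw values) for one confusion matrix."""
    rows = []
    for k, lab in enumerate(cm.labels):
        m = metrics_from_counts(class_counts(cm, k))
        name = CLASS_NAMES[lab] if isinstance(lab, (int, np.integer)) and \
            0 <= lab < len(CLASS_NAMES) else str(lab)
        rows.append({"class": name, **m,
                     "overall_accuracy": overall_accuracy(cm)})
    return pd.DataFrame(rows)


def scenario_report(results: dict[str, ConfusionMatrix],
                    rounded: bool = True) -> pd.DataFrame:
    """Consolidated report: one row per (scenario, class).

    Columns: method, class, precision, recall, f1, accuracy — the accuracy
    column repeats the scenario's multiclass accuracy on every class row.
    """
    if not results:
        raise ValueError("no scenarios to report")
    rows = []
    for method, cm in results.items():
        acc = overall_accuracy(cm)
        for k, lab in enumerate(cm.labels):
            m = metrics_from_counts(class_counts(cm, k))
            name = CLASS_NAMES[lab] if isinstance(lab, (int, np.integer)) and \
                0 <= lab < len(CLASS_NAMES) else str(lab)
            row = {"method": method, "class": name,
                   "precision": m["precision"], "recall": m["recall"],
                   "f1": m["f1"], "accuracy": acc}
            if rounded:
                for key in ("precision", "recall", "f1", "accuracy"):
                    row[key] = round4(row[key])
            rows.append(row)
    return pd.DataFrame(rows)


def plot_confusion(cm: ConfusionMatrix, path) -> None:
    """Optional PNG rendering of a confusion matrix (needs matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = [CLASS_NAMES[lab] if isinstance(lab, (int, np.integer)) else str(lab)
             for lab in cm.labels]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(cm.counts, cmap="Blues")
    ax.set_xticks(range(len(names)), names)
    ax.set_yticks(range(len(names)), names)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    for i in range(len(names)):
        for j in range(len(names)):
            ax.text(j, i, str(cm.counts[i, j]), ha="center", va="center")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
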