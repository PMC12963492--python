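"""Classifier evaluation: confusion matrix, per-class and macro metrics,
and one-vs-rest ROC AUC.

Conventions: confusion rows are the true class, columns the predicted
class; precision_k = cm[k,k]/colsum_k and recall_k = cm[k,k]/rowsum_k
with the zero-division convention "report 0 and flag".  AUC uses the
rank (Mann-Whitney) formulation with midranks for ties, which equals the
trapezoidal integral of the ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata


@dataclass
class ConfusionMatrix:
    matrix: np.ndarray          # (K, K) integer counts
    classes: list[str]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        k = len(self.classes)
        if self.matrix.shape != (k, k):
            raise ValueError(f"matrix shape {self.matrix.shape} != ({k}, {k})")
        if (self.matrix < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def support(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.matrix.sum())


def confusion(y_true, y_pred, classes: list[str]) -> ConfusionMatrix:
    """Count (true, predicted) pairs; unknown labels are fatal."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    index = {c: i for i, c in enumerate(classes)}
    k = len(classes)
    m = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        ti = index[t] if t in index else _fail(t)
        pi = index[p] if p in index else _fail(p)
        m[ti, pi] += 1
    return ConfusionMatrix(m, list(classes))


def _fail(label):
    raise KeyError(f"unknown class label {label!r}")


@dataclass
class ClassReport:
    classes: list[str]
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    accuracy: float
    zero_division_flags: list[str] = field(default_factory=list)

    @property
    def macro_precision(self) -> float:
        return float(self.precision.mean())

    @property
    def macro_recall(self) -> float:
        return float(self.recall.mean())

    @property
    def macro_f1(self) -> float:
        return float(self.f1.mean())

    @property
    def weighted_f1(self) -> float:
        w = self.support / max(self.support.sum(), 1)
        return float((self.f1 * w).sum())

    def to_text(self) -> str:
        lines = [f"{'Class':<26}{'Precision':>10}{'Recall':>8}{'F1':>7}{'Support':>9}"]
        for i, c in enumerate(self.classes):
            lines.append(f"{c:<26}{self.precision[i]:>10.2f}{self.recall[i]:>8.2f}"
                         f"{self.f1[i]:>7.2f}{int(self.support[i]):>9d}")
        lines.append(
            f"Overall: Accuracy = {self.accuracy:.4f}, "
            f"Macro P/R/F1 = {self.macro_precision:.2f}/{self.macro_recall:.2f}/{self.macro_f1:.2f}"
        )
        return "\n".join(lines)


def class_report(cm: ConfusionMatrix) -> ClassReport:
    """Per-class precision/recall/F1 plus macro averages and accuracy."""
    m = cm.matrix
    if m.sum() == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(m).astype(np.float64)
    col = m.sum(axis=0).astype(np.float64)
    row = m.sum(axis=1).astype(np.float64)
    flags = []
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, diag / np.maximum(col, 1e-300), 0.0)
        recall = np.where(row > 0, diag / np.maximum(row, 1e-300), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.maximum(denom, 1e-300), 0.0)
    for i, c in enumerate(cm.classes):
        if col[i] == 0:
            flags.append(f"{c}: no predictions (precision set to 0)")
        if row[i] == 0:
            flags.append(f"{c}: no support (recall set to 0)")
    accuracy = float(np.trace(m)) / float(m.sum())
    return ClassReport(list(cm.classes), precision, recall, f1, row.astype(np.int64),
                       accuracy, flags)


def roc_auc_ovr(scores: np.ndarray, y_true) -> dict:
    """One-vs-rest AUC per class (midrank Mann-Whitney) plus the macro mean.

    ``scores`` is (N, K); ``y_true`` holds class indices.  A class absent
    from ``y_true`` (or covering all samples) has undefined AUC, reported
    as NaN and excluded from the macro average.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    y_true = np.asarray(y_true)
    n, k = scores.shape
    out: dict = {"per_class": {}, "macro": np.nan}
    aucs = []
    for c in range(k):
        pos = y_true == c
        n_pos = int(pos.sum())
        n_neg = n - n_pos
        if n_pos == 0 or n_neg == 0:
            out["per_class"][c] = np.nan
            continue
        r = rankdata(scores[:, c])  # midranks
        auc = (r[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
        out["per_class"][c] = float(auc)
        aucs.append(auc)
    if aucs:
        out["macro"] = float(np.mean(aucs))
    return out


def plot_confusion(cm: ConfusionMatrix, path) -> None:
    """Confusion-matrix heatmap as PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(cm.matrix, cmap="Blues")
    ax.set_xticks(range(len(cm.classes)), cm.classes, rotation=90, fontsize=7)
    ax.set_yticks(range(len(cm.classes)), cm.classes, fontsize=7)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_roc(scores: np.ndarray, y_true, classes: list[str], path) -> None:
    """One-vs-rest ROC curves as PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.metrics import roc_curve

    y_true = np.asarray(y_true)
    fig, ax = plt.subplots(figsize=(6, 5))
    for c, name in enumerate(classes):
        if (y_true == c).any() and (y_true != c).any():
            fpr, tpr, _ = roc_curve(y_true == c, scores[:, c])
            ax.plot(fpr, tpr, lw=1, label=name)
    ax.plot([0, 1], [0, 1], "k--", lw=0.5)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
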