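"""Confusion-matrix construction and multiclass evaluation metrics.

All metrics derive from a K x K confusion matrix (rows = true class,
columns = predicted class) via one-vs-rest counts per class j:

    precision_j = TP_j / (TP_j + FP_j)
    recall_j    = TP_j / (TP_j + FN_j)
    F1_j        = 2 precision_j recall_j / (precision_j + recall_j)
    MCC_j       = (TP_j TN_j - FP_j FN_j) /
                  sqrt((TP_j+FP_j)(TP_j+FN_j)(TN_j+FP_j)(TN_j+FN_j))

Overall accuracy is trace/total; macro metrics are unweighted means over
the included classes (by default, classes with nonzero support — a class
absent from the evaluation split contributes no term).  Ratios with a zero
denominator are reported as 0.0 and flagged as undefined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class ConfusionMatrix:
    counts: np.ndarray                 # (K, K) ints, rows true, cols predicted
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")
        if not self.class_names:
            self.class_names = [f"class{i}" for i in range(self.counts.shape[0])]

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def support(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def one_vs_rest(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(TP, FP, FN, TN) vectors, one entry per class."""
        tp = np.diag(self.counts).astype(np.int64)
        fp = self.counts.sum(axis=0) - tp
        fn = self.counts.sum(axis=1) - tp
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn

    def to_csv(self, path: str | Path) -> None:
        header = "true\\pred," + ",".join(self.class_names)
        rows = [
            f"{name}," + ",".join(str(v) for v in row)
            for name, row in zip(self.class_names, self.counts)
        ]
        Path(path).write_text("\n".join([header, *rows]) + "\n")

    def to_heatmap(self, path: str | Path) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(self.counts, cmap="Blues")
        ax.set_xticks(range(self.n_classes), self.class_names, rotation=45, ha="right")
        ax.set_yticks(range(self.n_classes), self.class_names)
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        for i in range(self.n_classes):
            for j in range(self.n_classes):
                ax.text(j, i, str(self.counts[i, j]), ha="center", va="center", fontsize=7)
        fig.colorbar(im)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def build_confusion(y_true, y_pred, n_classes: int, class_names: list[str] | None = None) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        bad = np.nonzero((arr < 0) | (arr >= n_classes))[0]
        if bad.size:
            raise ValueError(f"{name}[{bad[0]}] = {arr[bad[0]]} outside [0, {n_classes - 1}]")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts, class_names or [])


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both vanish)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class ClassMetrics:
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    mcc: np.ndarray
    support: np.ndarray
    undefined: dict[str, np.ndarray]   # metric -> boolean mask of 0-denominator cases


def per_class_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    tp, fp, fn, tn = (v.astype(np.float64) for v in cm.one_vs_rest())

    def safe_div(num, den):
        mask = den == 0
        out = np.where(mask, 0.0, num / np.where(mask, 1.0, den))
        return out, mask

    precision, p_undef = safe_div(tp, tp + fp)
    recall, r_undef = safe_div(tp, tp + fn)
    f1 = np.array([f1_score(p, r) for p, r in zip(precision, recall)])
    mcc_den = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc, m_undef = safe_div(tp * tn - fp * fn, mcc_den)
    return ClassMetrics(
        precision=precision,
        recall=recall,
        f1=f1,
        mcc=mcc,
        support=cm.support(),
        undefined={"precision": p_undef, "recall": r_undef, "mcc": m_undef,
                   "f1": p_undef & r_undef},
    )


@dataclass
class MacroReport:
    overall_accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    macro_mcc: float
    per_class: ClassMetrics
    included_classes: np.ndarray
    class_names: list[str]

    def to_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "macro_mcc": self.macro_mcc,
            "included_classes": [self.class_names[i] for i in self.included_classes],
            "per_class": {
                self.class_names[i]: {
                    "precision": float(self.per_class.precision[i]),
                    "recall": float(self.per_class.recall[i]),
                    "f1": float(self.per_class.f1[i]),
                    "mcc": float(self.per_class.mcc[i]),
                    "support": int(self.per_class.support[i]),
                }
                for i in range(len(self.class_names))
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def to_table(self) -> str:
        """Report table: percentages to 1 decimal, F1/MCC to 3 decimals."""
        lines = [f"{'Class':<12}{'Precision(%)':>14}{'Recall(%)':>11}{'F1':>8}{'MCC':>8}"]
        pc = self.per_class
        for i in self.included_classes:
            lines.append(
                f"{self.class_names[i]:<12}{100 * pc.precision[i]:>14.1f}"
                f"{100 * pc.recall[i]:>11.1f}{pc.f1[i]:>8.3f}{pc.mcc[i]:>8.3f}"
            )
        lines.append(
            f"{'macro mean':<12}{100 * self.macro_precision:>14.1f}"
            f"{100 * self.macro_recall:>11.1f}{self.macro_f1:>8.3f}{self.macro_mcc:>8.3f}"
        )
        lines.append(f"overall accuracy: {100 * self.overall_accuracy:.1f}%")
        return "\n".join(lines)


def macro_report(
    cm: ConfusionMatrix,
    metrics: ClassMetrics | None = None,
    included_classes=None,
    include_empty_classes: bool = False,
) -> MacroReport:
    """Macro (unweighted) means over the included classes.

    By default classes with zero support are excluded; pass
    `include_empty_classes=True` to force their 0-valued inclusion, or give
    `included_classes` explicitly.
    """
    metrics = metrics or per_class_metrics(cm)
    if included_classes is None:
        if include_empty_classes:
            included = np.arange(cm.n_classes)
        else:
            included = np.nonzero(metrics.support > 0)[0]
    else:
        included = np.asarray(sorted(set(int(i) for i in included_classes)), dtype=int)
    if included.size == 0:
        raise ValueError("no classes included in the macro means")
    total = cm.total
    return MacroReport(
        overall_accuracy=float(np.trace(cm.counts)) / total if total else 0.0,
        macro_precision=float(metrics.precision[included].mean()),
        macro_recall=float(metrics.recall[included].mean()),
        macro_f1=float(metrics.f1[included].mean()),
        macro_mcc=float(metrics.mcc[included].mean()),
        per_class=metrics,
        included_classes=included,
        class_names=cm.class_names,
    )


def evaluate_predictions(y_true, y_pred, n_classes: int,
                         class_names: list[str] | None = None, **kwargs) -> MacroReport:
    """Convenience: labels -> confusion matrix -> macro report."""
    cm = build_confusion(y_true, y_pred, n_classes, class_names)
    return macro_report(cm, **kwargs)
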