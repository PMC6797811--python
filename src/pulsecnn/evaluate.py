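"""Confusion-matrix evaluation: per-class precision/recall/F-measure, accuracy.

Rows of the confusion matrix are true classes, columns predicted classes.
For class c, TP = cm[c][c], FP = column sum - TP, FN = row sum - TP;
precision = TP/(TP+FP), recall = TP/(TP+FN), F = 2PR/(P+R).  Overall
accuracy is trace/total; overall precision/recall/F are reported both as
unweighted (macro) class means and in micro form (which, for a full
confusion matrix, all collapse to the accuracy).  On balanced test sets the
macro recall equals the accuracy, so a single "overall" figure is coherent.

Divisions by zero (a class never predicted, or absent from the test set)
yield 0 with an explicit flag instead of NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "VocabularyError",
    "EmptyEvaluationError",
    "confusion_matrix",
    "metrics_from_confusion",
    "render_report",
    "round_half_up",
]


class VocabularyError(ValueError):
    """A label outside the declared label set was encountered."""


class EmptyEvaluationError(ValueError):
    """The confusion matrix contains no observations."""


@dataclass
class ConfusionMatrix:
    counts: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be K x K for K labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class EvaluationReport:
    cm: ConfusionMatrix
    per_class: dict[str, dict[str, float]]          # label -> precision/recall/f_measure
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f_measure: float
    micro_precision: float
    micro_recall: float
    micro_f_measure: float
    zero_division_flags: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)


def confusion_matrix(
    y_true: Sequence, y_pred: Sequence, labels: Sequence[str]
) -> ConfusionMatrix:
    """count[i][j] = number of samples with true label i predicted as j."""
    labels = list(labels)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    index = {lab: i for i, lab in enumerate(labels)}
    k = len(labels)
    counts = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise VocabularyError(f"label pair ({t!r}, {p!r}) outside declared labels")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, labels)


def metrics_from_confusion(cm: ConfusionMatrix, metadata: Mapping | None = None) -> EvaluationReport:
    counts = cm.counts
    total = counts.sum()
    if total == 0:
        raise EmptyEvaluationError("confusion matrix is empty")

    tp = np.diag(counts).astype(float)
    col = counts.sum(axis=0).astype(float)
    row = counts.sum(axis=1).astype(float)
    fp = col - tp
    fn = row - tp

    flags: list[str] = []
    per_class: dict[str, dict[str, float]] = {}
    precisions, recalls, fs = [], [], []
    for i, lab in enumerate(cm.labels):
        if tp[i] + fp[i] > 0:
            p = tp[i] / (tp[i] + fp[i])
        else:
            p, _ = 0.0, flags.append(f"precision[{lab}]: class never predicted")
        if tp[i] + fn[i] > 0:
            r = tp[i] / (tp[i] + fn[i])
        else:
            r, _ = 0.0, flags.append(f"recall[{lab}]: class absent from test set")
        if p + r > 0:
            f = 2 * p * r / (p + r)
        else:
            f, _ = 0.0, flags.append(f"f_measure[{lab}]: precision + recall = 0")
        per_class[lab] = {"precision": p, "recall": r, "f_measure": f}
        precisions.append(p)
        recalls.append(r)
        fs.append(f)

    accuracy = float(tp.sum() / total)
    return EvaluationReport(
        cm=cm,
        per_class=per_class,
        accuracy=accuracy,
        macro_precision=float(np.mean(precisions)),
        macro_recall=float(np.mean(recalls)),
        macro_f_measure=float(np.mean(fs)),
        micro_precision=accuracy,
        micro_recall=accuracy,
        micro_f_measure=accuracy,
        zero_division_flags=flags,
        metadata=dict(metadata or {}),
    )


def round_half_up(x: float, places: int = 2) -> float:
    """Round-half-up (0.945 -> 0.95), unlike Python's banker's rounding."""
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def render_report(report: EvaluationReport, history=None, out_dir: str | Path = ".") -> dict[str, Path]:
    """Write metrics/confusion/learning-curve artifacts.

    ``metrics.csv`` is the human-readable table rounded half-up to two
    decimals (one row per class plus an overall row); ``metrics_full.csv``
    keeps full precision and both macro and micro overall figures;
    ``confusion.csv`` carries the raw counts; ``curves.csv`` the per-epoch
    cost / train error / test error when a history is supplied.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    rows = [
        {"pattern": lab,
         "precision": round_half_up(m["precision"]),
         "recall": round_half_up(m["recall"]),
         "f_measure": round_half_up(m["f_measure"])}
        for lab, m in report.per_class.items()
    ]
    rows.append({
        "pattern": "overall",
        "precision": round_half_up(report.macro_precision),
        "recall": round_half_up(report.macro_recall),
        "f_measure": round_half_up(report.macro_f_measure),
    })
    paths["metrics"] = out / "metrics.csv"
    pd.DataFrame(rows).to_csv(paths["metrics"], index=False)

    full_rows = [
        {"pattern": lab, **m} for lab, m in report.per_class.items()
    ] + [
        {"pattern": "overall_macro", "precision": report.macro_precision,
         "recall": report.macro_recall, "f_measure": report.macro_f_measure},
        {"pattern": "overall_micro", "precision": report.micro_precision,
         "recall": report.micro_recall, "f_measure": report.micro_f_measure},
    ]
    full = pd.DataFrame(full_rows)
    full["accuracy"] = report.accuracy
    paths["metrics_full"] = out / "metrics_full.csv"
    full.to_csv(paths["metrics_full"], index=False)

    cmdf = pd.DataFrame(report.cm.counts, index=report.cm.labels, columns=report.cm.labels)
    cmdf.index.name = "true\\pred"
    paths["confusion"] = out / "confusion.csv"
    cmdf.to_csv(paths["confusion"])

    if history is not None:
        curves = pd.DataFrame({
            "epoch": np.arange(len(history.cost)),
            "cost": history.cost,
            "train_error": history.train_error,
            "test_error": history.test_error,
        })
        paths["curves"] = out / "curves.csv"
        curves.to_csv(paths["curves"], index=False)
        try:  # plot is a convenience; matplotlib is optional
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, ax = plt.subplots(figsize=(6, 4))
            ax.plot(curves["epoch"], curves["cost"], label="cost")
            ax.plot(curves["epoch"], curves["train_error"], label="training error")
            ax.plot(curves["epoch"], curves["test_error"], label="test error")
            ax.axvline(history.best_epoch, ls="--", c="gray", lw=0.8)
            ax.set_xlabel("epoch")
            ax.legend()
            fig.tight_layout()
            fig.savefig(out / "curves.png", dpi=100)
            plt.close(fig)
            paths["curves_png"] = out / "curves.png"
        except Exception:
            pass
    return paths
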