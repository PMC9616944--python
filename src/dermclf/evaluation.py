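"""Multi-class evaluation: classification reports and k-fold cross-validation.

Metrics follow the standard single-label multi-class definitions:
per-class precision TP/(TP+FP), recall TP/(TP+FN), F1 their harmonic mean;
macro averages weight classes equally, weighted averages weight by support
(which makes weighted recall identically equal to accuracy).  Zero
denominators yield 0 with a logged warning.  Cross-validated accuracy is
the arithmetic mean of the per-fold accuracies, not the accuracy of any
single fold's model.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold

from .errors import ValidationError
from .preprocess import LabelCodec

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    support: int


@dataclass(frozen=True)
class EvalReport:
    """Accuracy, per-class P/R/F1/support, macro & weighted averages, confusion."""

    accuracy: float
    per_class: dict[str, ClassMetrics]
    macro_avg: tuple[float, float, float]
    weighted_avg: tuple[float, float, float]
    confusion: np.ndarray  # rows = true class, cols = predicted, codec order
    classes: tuple[str, ...]

    @property
    def total(self) -> int:
        return sum(m.support for m in self.per_class.values())

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class": {
                c: {"precision": m.precision, "recall": m.recall, "f1": m.f1, "support": m.support}
                for c, m in self.per_class.items()
            },
            "macro_avg": list(self.macro_avg),
            "weighted_avg": list(self.weighted_avg),
            "confusion": self.confusion.tolist(),
            "classes": list(self.classes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvalReport":
        return cls(
            accuracy=d["accuracy"],
            per_class={
                c: ClassMetrics(m["precision"], m["recall"], m["f1"], m["support"])
                for c, m in d["per_class"].items()
            },
            macro_avg=tuple(d["macro_avg"]),
            weighted_avg=tuple(d["weighted_avg"]),
            confusion=np.asarray(d["confusion"]),
            classes=tuple(d["classes"]),
        )


def classification_report(y_true, y_pred, codec: LabelCodec | None = None) -> EvalReport:
    """Full multi-class report over the codec's class order."""
    codec = codec or LabelCodec()
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValidationError(f"{len(y_true)} true vs {len(y_pred)} predicted labels")
    for lab in set(y_true) | set(y_pred):
        codec.index(lab)  # raises LabelError on unknown codes
    labels = list(codec.classes)
    p, r, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0
    )
    if (np.asarray(support) > 0).any() and ((p == 0) & (np.asarray(support) > 0)).any():
        degenerate = [labels[i] for i in np.flatnonzero((p == 0) & (np.asarray(support) > 0))]
        logger.warning("zero precision (class never predicted correctly?): %s", degenerate)
    mp, mr, mf1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average="macro", zero_division=0
    )
    wp, wr, wf1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average="weighted", zero_division=0
    )
    conf = confusion_matrix(y_true, y_pred, labels=labels)
    accuracy = float(np.trace(conf)) / len(y_true) if y_true else 0.0
    return EvalReport(
        accuracy=accuracy,
        per_class={
            c: ClassMetrics(float(p[i]), float(r[i]), float(f1[i]), int(support[i]))
            for i, c in enumerate(labels)
        },
        macro_avg=(float(mp), float(mr), float(mf1)),
        weighted_avg=(float(wp), float(wr), float(wf1)),
        confusion=conf,
        classes=tuple(labels),
    )


@dataclass(frozen=True)
class CVResult:
    """Fold count, per-fold accuracies and their arithmetic mean."""

    k: int
    fold_accuracies: tuple[float, ...]
    mean_accuracy: float

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "fold_accuracies": list(self.fold_accuracies),
            "mean_accuracy": self.mean_accuracy,
        }


def kfold_cv(ids, labels, k: int, trainer, seed: int = 42) -> CVResult:
    """Stratified k-fold cross-validation.

    ``trainer(train_ids, test_ids)`` must return predicted labels aligned
    with ``test_ids``; fold accuracy is computed against the true labels
    and the reported accuracy is the mean over folds.  Every sample is a
    test item in exactly one fold.
    """
    ids = np.asarray(list(ids))
    labels = np.asarray(list(labels))
    if len(ids) != len(labels):
        raise ValidationError(f"{len(ids)} ids vs {len(labels)} labels")
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")
    counts = {c: int((labels == c).sum()) for c in set(labels.tolist())}
    too_small = {c: n for c, n in counts.items() if n < k}
    if too_small:
        raise ValidationError(f"class count(s) below k={k}: {too_small}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_accs = []
    for train_idx, test_idx in skf.split(ids, labels):
        y_pred = np.asarray(trainer(ids[train_idx].tolist(), ids[test_idx].tolist()))
        if len(y_pred) != len(test_idx):
            raise ValidationError("trainer returned wrong number of predictions")
        fold_accs.append(float(np.mean(y_pred == labels[test_idx])))
    return CVResult(k=k, fold_accuracies=tuple(fold_accs), mean_accuracy=float(np.mean(fold_accs)))


def _report_text(report: EvalReport) -> str:
    width = max(len(c) for c in report.classes) + 2
    lines = [f"{'':{width}}{'precision':>10}{'recall':>10}{'f1-score':>10}{'support':>10}", ""]
    for c in report.classes:
        m = report.per_class[c]
        lines.append(
            f"{c:{width}}{m.precision:>10.2f}{m.recall:>10.2f}{m.f1:>10.2f}{m.support:>10d}"
        )
    lines.append("")
    lines.append(f"{'accuracy':{width}}{'':>20}{report.accuracy:>10.2f}{report.total:>10d}")
    for name, avg in (("macro avg", report.macro_avg), ("weighted avg", report.weighted_avg)):
        lines.append(
            f"{name:{width}}{avg[0]:>10.2f}{avg[1]:>10.2f}{avg[2]:>10.2f}{report.total:>10d}"
        )
    return "\n".join(lines) + "\n"


def _cv_text(result: CVResult) -> str:
    lines = [f"{'fold':>6}{'accuracy':>12}"]
    for i, acc in enumerate(result.fold_accuracies, 1):
        lines.append(f"{i:>6d}{acc:>12.4f}")
    lines.append(f"{'mean':>6}{result.mean_accuracy:>12.4f}")
    return "\n".join(lines) + "\n"


def render_report(report: EvalReport | CVResult, path) -> None:
    """Write ``<path>.json`` and ``<path>.txt`` renderings of a report."""
    path = Path(path)
    base = path.with_suffix("") if path.suffix in (".json", ".txt") else path
    payload = report.to_dict()
    base.with_suffix(".json").write_text(json.dumps(payload, indent=2))
    text = _report_text(report) if isinstance(report, EvalReport) else _cv_text(report)
    base.with_suffix(".txt").write_text(text)


def confusion_to_csv(report: EvalReport, path) -> None:
    header = "," + ",".join(report.classes)
    rows = [
        f"{c}," + ",".join(str(int(v)) for v in report.confusion[i])
        for i, c in enumerate(report.classes)
    ]
    Path(path).write_text(header + "\n" + "\n".join(rows) + "\n")
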