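"""Confusion-matrix metrics for the three-class problem.

Rows are true classes, columns predicted, in the fixed order (Benign,
Malignant, Normal).  Per-class precision, recall and F1 are one-vs-rest:

    P = Tp / (Tp + Fp)      R = Tp / (Tp + Fn)      F1 = 2PR / (P + R)

and overall accuracy is the diagonal sum over the total.  Class-wise
accuracy (per-true-class correct fraction) is numerically identical to
per-class recall.  Zero denominators yield a flagged 0.0 sentinel instead of
NaN.  Display rounding follows the reporting convention used throughout:
one decimal for percentages, two decimals for class-wise accuracies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .manifest import CLASS_INDEX, CLASS_NAMES


@dataclass
class ClassMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float
    undefined: bool = False  # any zero-denominator sentinel applied


@dataclass
class MetricReport:
    per_class: dict[str, ClassMetrics]
    accuracy: float
    total: int


def confusion(true_labels: list[str], predicted_labels: list[str]) -> np.ndarray:
    """3x3 confusion counts: entry (i, j) = samples of true class i predicted j."""
    if len(true_labels) != len(predicted_labels):
        raise ValidationError(
            f"label list lengths differ: {len(true_labels)} vs {len(predicted_labels)}"
        )
    cm = np.zeros((3, 3), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        if t not in CLASS_INDEX or p not in CLASS_INDEX:
            raise ValidationError(f"unknown label in pair ({t!r}, {p!r})")
        cm[CLASS_INDEX[t], CLASS_INDEX[p]] += 1
    return cm


def _validate_cm(cm: np.ndarray) -> np.ndarray:
    cm = np.asarray(cm)
    if cm.shape != (3, 3):
        raise ValidationError(f"confusion matrix must be 3x3, got {cm.shape}")
    if np.any(cm < 0) or not np.issubdtype(cm.dtype, np.integer):
        raise ValidationError("confusion matrix must hold non-negative integers")
    return cm.astype(np.int64)


def compute_metrics(cm: np.ndarray) -> MetricReport:
    """One-vs-rest per-class metrics plus overall accuracy from counts."""
    cm = _validate_cm(cm)
    total = int(cm.sum())
    if total == 0:
        raise ValidationError("confusion matrix is all zeros")
    per_class: dict[str, ClassMetrics] = {}
    for i, name in enumerate(CLASS_NAMES):
        tp = int(cm[i, i])
        fp = int(cm[:, i].sum() - tp)
        fn = int(cm[i, :].sum() - tp)
        tn = total - tp - fp - fn
        undefined = False
        if tp + fp > 0:
            precision = tp / (tp + fp)
        else:
            precision, undefined = 0.0, True
        if tp + fn > 0:
            recall = tp / (tp + fn)
        else:
            recall, undefined = 0.0, True
        if precision + recall > 0:
            f1 = 2 * precision * recall / (precision + recall)
        else:
            f1, undefined = 0.0, True
        per_class[name] = ClassMetrics(tp, fp, fn, tn, precision, recall, f1, undefined)
    accuracy = float(np.trace(cm) / total)
    return MetricReport(per_class=per_class, accuracy=accuracy, total=total)


def classwise_accuracy(cm: np.ndarray) -> dict[str, float | None]:
    """Per-true-class correct fraction; ``None`` flags an empty class row."""
    cm = _validate_cm(cm)
    out: dict[str, float | None] = {}
    for i, name in enumerate(CLASS_NAMES):
        row = int(cm[i, :].sum())
        out[name] = float(cm[i, i] / row) if row > 0 else None
    return out


def macro_precision_recall(report: MetricReport) -> tuple[float, float]:
    """Unweighted class averages of precision and recall."""
    ps = [m.precision for m in report.per_class.values()]
    rs = [m.recall for m in report.per_class.values()]
    return float(np.mean(ps)), float(np.mean(rs))


def report_to_dict(report: MetricReport, cm: np.ndarray) -> dict:
    """JSON-ready mirror of the report (exact values, not rounded)."""
    cw = classwise_accuracy(cm)
    return {
        "class_order": list(CLASS_NAMES),
        "confusion_matrix": np.asarray(cm).tolist(),
        "overall_accuracy": report.accuracy,
        "per_class": {
            name: {
                "tp": m.tp, "fp": m.fp, "fn": m.fn, "tn": m.tn,
                "precision": m.precision, "recall": m.recall, "f1": m.f1,
                "classwise_accuracy": cw[name],
                "undefined": m.undefined,
            }
            for name, m in report.per_class.items()
        },
        "total": report.total,
    }


def render_report(report: MetricReport, cm: np.ndarray, as_json: bool = False) -> str:
    """Human-readable table (or its JSON mirror) of the evaluation results.

    Percentages print with one decimal; class-wise accuracies with two.
    Metrics flagged undefined render as ``n/a``.
    """
    if as_json:
        return json.dumps(report_to_dict(report, cm), indent=2, sort_keys=True)
    cm = _validate_cm(cm)
    cw = classwise_accuracy(cm)
    lines = ["Confusion matrix (rows = true, columns = predicted)"]
    header = "            " + "".join(f"{n:>11}" for n in CLASS_NAMES)
    lines.append(header)
    for i, name in enumerate(CLASS_NAMES):
        lines.append(f"{name:>12}" + "".join(f"{int(v):>11}" for v in cm[i]))
    lines.append("")
    lines.append(f"{'Class':>12}{'P (%)':>9}{'R (%)':>9}{'F1 (%)':>9}{'Acc (%)':>10}")
    for name, m in report.per_class.items():
        if m.undefined:
            p = r = f = "n/a"
        else:
            p, r, f = (f"{100*m.precision:.1f}", f"{100*m.recall:.1f}", f"{100*m.f1:.1f}")
        acc = f"{100*cw[name]:.2f}" if cw[name] is not None else "n/a"
        lines.append(f"{name:>12}{p:>9}{r:>9}{f:>9}{acc:>10}")
    lines.append("")
    lines.append(f"Overall accuracy: {100*report.accuracy:.1f}% ({np.trace(cm)}/{report.total})")
    lines.append("Note: recall is computed as Tp/(Tp+Fn).")
    return "\n".join(lines)
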