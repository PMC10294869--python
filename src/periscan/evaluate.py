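"""2×2 confusion matrices in the clinical-table convention.

Tables report counts with percent-of-total in parentheses, a per-row
subtotal (the fraction of that output row that is correct — precision
for the positive row), per-column subtotals (the recall of each target
class) and overall accuracy in the corner. Metrics are kept both raw
and rounded half-up to one decimal percent; displayed values are the
rounded ones, comparisons should use the raw ones.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix2x2",
    "confusion_from_predictions",
    "matrix_metrics",
    "render_matrix_table",
    "parse_matrix_table",
]


@dataclass
class ConfusionMatrix2x2:
    tp: int
    fp: int
    fn: int
    tn: int
    positive_name: str = "Damaged"
    negative_name: str = "Healthy"

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_from_predictions(predicted, truth, positive="damaged",
                               positive_name: str | None = None,
                               negative_name: str | None = None) -> ConfusionMatrix2x2:
    """Count a 2×2 matrix from paired binary label sequences."""
    predicted = list(predicted)
    truth = list(truth)
    if len(predicted) != len(truth):
        raise ValueError(
            f"length mismatch: {len(predicted)} predictions vs {len(truth)} truths")
    labels = set(predicted) | set(truth)
    if len(labels) > 2:
        raise ValueError(f"labels must be binary, got {sorted(labels)}")
    tp = fp = fn = tn = 0
    for p, t in zip(predicted, truth):
        if p == positive and t == positive:
            tp += 1
        elif p == positive:
            fp += 1
        elif t == positive:
            fn += 1
        else:
            tn += 1
    names = {}
    if positive_name:
        names["positive_name"] = positive_name
    if negative_name:
        names["negative_name"] = negative_name
    return ConfusionMatrix2x2(tp=tp, fp=fp, fn=fn, tn=tn, **names)


def _round1(x: float) -> float:
    """Half-up rounding to one decimal (90.45 -> 90.5)."""
    return int(x * 10 + 0.5) / 10.0


def matrix_metrics(cm: ConfusionMatrix2x2) -> dict:
    """Accuracy, precision, the two recalls, row subtotals and cell
    percentages, all as raw percent values plus rounded display copies.

    A ratio with a zero denominator is reported as ``None`` (flagged
    undefined) rather than raising.
    """
    if cm.total <= 0:
        raise ValueError("empty matrix has no metrics")

    def ratio(num, den):
        return None if den == 0 else 100.0 * num / den

    metrics = {
        "accuracy": ratio(cm.tp + cm.tn, cm.total),
        "precision": ratio(cm.tp, cm.tp + cm.fp),
        "recall_positive": ratio(cm.tp, cm.tp + cm.fn),
        "recall_negative": ratio(cm.tn, cm.tn + cm.fp),
        "row_subtotals": {
            cm.positive_name: ratio(cm.tp, cm.tp + cm.fp),
            cm.negative_name: ratio(cm.tn, cm.tn + cm.fn),
        },
        "cell_percentages": {
            "tp": 100.0 * cm.tp / cm.total,
            "fp": 100.0 * cm.fp / cm.total,
            "fn": 100.0 * cm.fn / cm.total,
            "tn": 100.0 * cm.tn / cm.total,
        },
    }
    metrics["rounded"] = {
        k: (None if v is None else _round1(v))
        for k, v in metrics.items()
        if k in ("accuracy", "precision", "recall_positive", "recall_negative")
    }
    return metrics


def render_matrix_table(cm: ConfusionMatrix2x2) -> str:
    """Render the matrix in the counts-with-percentages table layout."""
    m = matrix_metrics(cm)

    def cell(count):
        return f"{count} ({_round1(100.0 * count / cm.total)}%)"

    def pct(v):
        return "n/a" if v is None else f"{_round1(v)}%"

    pos, neg = cm.positive_name, cm.negative_name
    lines = [
        f"Category\t{pos}\t{neg}\tSubtotal",
        f"{pos}\t{cell(cm.tp)}\t{cell(cm.fp)}\t{pct(m['precision'])}",
        f"{neg}\t{cell(cm.fn)}\t{cell(cm.tn)}\t{pct(m['row_subtotals'][neg])}",
        f"Subtotal\t{pct(m['recall_positive'])}\t{pct(m['recall_negative'])}\t{pct(m['accuracy'])}",
    ]
    return "\n".join(lines)


_CELL_RE = re.compile(r"^(\d+) \(")


def parse_matrix_table(text: str) -> ConfusionMatrix2x2:
    """Recover the counts from a table produced by render_matrix_table."""
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    header = lines[0].split("\t")
    pos, neg = header[1], header[2]
    row1 = lines[1].split("\t")
    row2 = lines[2].split("\t")

    def count(s):
        match = _CELL_RE.match(s)
        if not match:
            raise ValueError(f"unparseable cell: {s!r}")
        return int(match.group(1))

    return ConfusionMatrix2x2(tp=count(row1[1]), fp=count(row1[2]),
                              fn=count(row2[1]), tn=count(row2[2]),
                              positive_name=pos, negative_name=neg)
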