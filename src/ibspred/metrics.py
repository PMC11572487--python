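"""Confusion-matrix evaluation for imbalanced binary residue classification.

With only ~3 % of residues membrane-interacting, accuracy is useless; the
metrics of record are the F1 score and the Matthews correlation
coefficient (MCC), both functions of the confusion matrix, with precision
reported separately for structure-aware post-processing:

    F1  = 2·TP / (2·TP + FP + FN)
    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Degenerate denominators return 0 by convention so per-protein reports
stay total.  Reports are produced pooled over all residues and keyed per
protein; pooled confusion counts are the elementwise sum of the
per-protein ones.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "confusion",
    "f1_score",
    "mcc_score",
    "precision_score",
    "recall_score",
    "evaluate_predictions",
    "write_report",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/FN/TN counts; positive class = membrane-interacting."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a nonnegative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
        )


def confusion(true_labels, predicted_labels) -> ConfusionMatrix:
    """Count TP/FP/FN/TN for two equal-length binary vectors."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    for arr, name in ((t, "true"), (p, "predicted")):
        bad = set(np.unique(arr)) - {0, 1}
        if bad:
            raise ValueError(f"non-binary {name} labels: {bad}")
    return ConfusionMatrix(
        tp=int(np.sum((t == 1) & (p == 1))),
        fp=int(np.sum((t == 0) & (p == 1))),
        fn=int(np.sum((t == 1) & (p == 0))),
        tn=int(np.sum((t == 0) & (p == 0))),
    )


def f1_score(cm: ConfusionMatrix) -> float:
    denom = 2 * cm.tp + cm.fp + cm.fn
    return 2 * cm.tp / denom if denom else 0.0


def mcc_score(cm: ConfusionMatrix) -> float:
    denom = math.sqrt(
        float(cm.tp + cm.fp)
        * float(cm.tp + cm.fn)
        * float(cm.tn + cm.fp)
        * float(cm.tn + cm.fn)
    )
    if denom == 0.0:
        return 0.0
    return (float(cm.tp) * cm.tn - float(cm.fp) * cm.fn) / denom


def precision_score(cm: ConfusionMatrix) -> float:
    denom = cm.tp + cm.fp
    return cm.tp / denom if denom else 0.0


def recall_score(cm: ConfusionMatrix) -> float:
    denom = cm.tp + cm.fn
    return cm.tp / denom if denom else 0.0


@dataclass
class MetricReport:
    """Pooled metrics plus a per-protein breakdown."""

    confusion: ConfusionMatrix
    f1: float
    mcc: float
    precision: float
    recall: float
    per_protein: dict[str, "MetricReport"] = field(default_factory=dict)

    @classmethod
    def from_confusion(cls, cm: ConfusionMatrix) -> "MetricReport":
        return cls(
            confusion=cm,
            f1=f1_score(cm),
            mcc=mcc_score(cm),
            precision=precision_score(cm),
            recall=recall_score(cm),
        )


def evaluate_predictions(
    true_by_protein: Mapping[str, np.ndarray],
    pred_by_protein: Mapping[str, np.ndarray],
) -> MetricReport:
    """Pooled + per-protein metric report from per-protein label vectors."""
    if not true_by_protein:
        raise ValueError("nothing to evaluate")
    if set(true_by_protein) != set(pred_by_protein):
        raise ValueError("true and predicted protein sets differ")
    per: dict[str, MetricReport] = {}
    pooled = ConfusionMatrix(0, 0, 0, 0)
    for pid in sorted(true_by_protein):
        cm = confusion(true_by_protein[pid], pred_by_protein[pid])
        per[pid] = MetricReport.from_confusion(cm)
        pooled = pooled + cm
    report = MetricReport.from_confusion(pooled)
    report.per_protein = per
    return report


def _rows(report: MetricReport):
    def row(scope, r):
        cm = r.confusion
        return {
            "scope": scope,
            "tp": cm.tp,
            "fp": cm.fp,
            "fn": cm.fn,
            "tn": cm.tn,
            "precision": r.precision,
            "recall": r.recall,
            "f1": r.f1,
            "mcc": r.mcc,
        }

    yield row("pooled", report)
    for pid, sub in report.per_protein.items():
        yield row(pid, sub)


def write_report(path: str | Path, report: MetricReport) -> None:
    """Write the TSV report and its JSON twin (same stem, .json suffix)."""
    path = Path(path)
    df = pd.DataFrame(list(_rows(report)))
    df.to_csv(path, sep="\t", index=False)
    with open(path.with_suffix(".json"), "w", encoding="utf-8") as fh:
        json.dump(df.to_dict(orient="records"), fh, indent=1)
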