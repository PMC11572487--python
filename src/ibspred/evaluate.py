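"""Model evaluation over residue datasets: pooled and per-protein reports."""

from __future__ import annotations

import numpy as np

from .features import ResidueDataset
from .metrics import MetricReport, evaluate_predictions
from .models import ResidueClassifier

__all__ = ["evaluate_model", "predictions_by_protein"]


def predictions_by_protein(
    model: ResidueClassifier, dataset: ResidueDataset, threshold: float | None = None
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Per-protein (true, predicted) label vectors for a dataset subset."""
    if len(dataset) == 0:
        raise ValueError("empty dataset subset")
    pred = model.predict(dataset.X, threshold=threshold)
    true_by, pred_by = {}, {}
    for pid, grp in dataset.meta.groupby("protein_id", sort=True):
        idx = grp.index.to_numpy()
        order = np.argsort(grp["position"].to_numpy())
        true_by[pid] = grp["label"].to_numpy(dtype=np.int8)[order]
        pred_by[pid] = pred[idx[order]]
    return true_by, pred_by


def evaluate_model(
    model: ResidueClassifier, dataset: ResidueDataset, threshold: float | None = None
) -> MetricReport:
    """Pooled + per-protein F1/MCC/precision/recall for one dataset subset."""
    true_by, pred_by = predictions_by_protein(model, dataset, threshold)
    return evaluate_predictions(true_by, pred_by)
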