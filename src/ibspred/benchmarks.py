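"""Reference confusion matrices for the five classifier families.

These are the published per-residue test-set confusion matrices for
membrane-interface classifiers trained on embeddings from two protein
language models (ProtTrans, D=1024; ESM-2 650M, D=1280) over full
database sequences.  The test set holds 41 proteins with 7776 residues,
so every matrix sums to 7776.  They serve as worked examples for the
metric functions: recomputing F1 and MCC from the counts reproduces the
published scores at two decimals.
"""

from __future__ import annotations

from .metrics import ConfusionMatrix

TEST_SET_RESIDUES = 7776
TEST_SET_PROTEINS = 41

# (tp, fp, fn, tn) per family, by embedding backend
REFERENCE_CONFUSIONS: dict[str, dict[str, ConfusionMatrix]] = {
    "prottrans": {
        "xgboost": ConfusionMatrix(534, 438, 330, 6474),
        "lgbm": ConfusionMatrix(579, 275, 285, 6637),
        "balanced_rf": ConfusionMatrix(604, 828, 260, 6084),
        "slp": ConfusionMatrix(508, 175, 356, 6737),
        "mlp": ConfusionMatrix(539, 182, 325, 6730),
    },
    "esm": {
        "xgboost": ConfusionMatrix(266, 177, 598, 6735),
        "lgbm": ConfusionMatrix(500, 496, 364, 6416),
        "balanced_rf": ConfusionMatrix(442, 743, 422, 6169),
        "slp": ConfusionMatrix(338, 97, 526, 6815),
        "mlp": ConfusionMatrix(421, 156, 443, 6756),
    },
}

# published scores, rounded to two decimals as printed
REFERENCE_SCORES: dict[str, dict[str, dict[str, float]]] = {
    "prottrans": {
        "xgboost": {"f1": 0.58, "mcc": 0.53},
        "lgbm": {"f1": 0.67, "mcc": 0.63},
        "balanced_rf": {"f1": 0.53, "mcc": 0.47},
        "slp": {"f1": 0.66, "mcc": 0.63},
        "mlp": {"f1": 0.68, "mcc": 0.65},
    },
    "esm": {
        "xgboost": {"f1": 0.41, "mcc": 0.38},
        "lgbm": {"f1": 0.54, "mcc": 0.48},
        "balanced_rf": {"f1": 0.43, "mcc": 0.35},
        "slp": {"f1": 0.52, "mcc": 0.52},
        "mlp": {"f1": 0.58, "mcc": 0.56},
    },
}
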