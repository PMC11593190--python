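"""Published benchmark metrics for the 13 evaluation scenarios.

Reference per-class precision/recall/F1 and multiclass accuracy reported
for 3-class NSCLC tile classification on the LC25000 lung subset (3,000
test tiles, 1,000 per class), for each feature-set / classifier
combination.  These values serve as inputs to metric-identity checks —
e.g. that the harmonic mean of a row's precision and recall reproduces
its F1 at 4-decimal rounding, and that the per-class recalls reproduce
the reported multiclass accuracy — they are not outputs of this package.
"""
from __future__ import annotations

import pandas as pd

#: Test tiles per class in the benchmark protocol.
TEST_TILES_PER_CLASS = 1000

#: (method, class, precision, recall, f1, accuracy) per scenario row.
_ROWS = [
    ("EfficientNet-B0", "LACA", 0.9742, 0.9080, 0.9399, 0.9613),
    ("EfficientNet-B0", "benign", 1.0, 1.0, 1.0, 0.9613),
    ("EfficientNet-B0", "LSCC", 0.9138, 0.9760, 0.9439, 0.9613),
    ("EfficientNet-B0 + LR", "LACA", 0.9693, 0.9170, 0.9424, 0.9627),
    ("EfficientNet-B0 + LR", "benign", 1.0, 1.0, 1.0, 0.9627),
    ("EfficientNet-B0 + LR", "LSCC", 0.9212, 0.9710, 0.9454, 0.9627),
    ("EfficientNet-B0 + SVM", "LACA", 0.9571, 0.9390, 0.9480, 0.9657),
    ("EfficientNet-B0 + SVM", "benign", 1.0, 1.0, 1.0, 0.9657),
    ("EfficientNet-B0 + SVM", "LSCC", 0.9401, 0.9580, 0.9489, 0.9657),
    ("EfficientNet-B0 + LGBM", "LACA", 0.9493, 0.9380, 0.9436, 0.9623),
    ("EfficientNet-B0 + LGBM", "benign", 0.9980, 1.0, 0.9990, 0.9623),
    ("EfficientNet-B0 + LGBM", "LSCC", 0.9396, 0.9490, 0.9442, 0.9623),
    ("EfficientNet-B0 + XGBoost", "LACA", 0.9352, 0.9530, 0.9440, 0.9620),
    ("EfficientNet-B0 + XGBoost", "benign", 0.9980, 1.0, 0.9990, 0.9620),
    ("EfficientNet-B0 + XGBoost", "LSCC", 0.9530, 0.9330, 0.9429, 0.9620),
    ("EfficientNet-B0 + LBP + LR", "LACA", 0.9809, 0.9290, 0.9542, 0.9703),
    ("EfficientNet-B0 + LBP + LR", "benign", 1.0, 1.0, 1.0, 0.9703),
    ("EfficientNet-B0 + LBP + LR", "LSCC", 0.9325, 0.9820, 0.9566, 0.9703),
    ("EfficientNet-B0 + LBP + SVM", "LACA", 0.9672, 0.9460, 0.9565, 0.9713),
    ("EfficientNet-B0 + LBP + SVM", "benign", 1.0, 1.0, 1.0, 0.9713),
    ("EfficientNet-B0 + LBP + SVM", "LSCC", 0.9471, 0.9680, 0.9574, 0.9713),
    ("EfficientNet-B0 + LBP + LGBM", "LACA", 0.9603, 0.9450, 0.9526, 0.9683),
    ("EfficientNet-B0 + LBP + LGBM", "benign", 0.9970, 1.0, 0.9985, 0.9683),
    ("EfficientNet-B0 + LBP + LGBM", "LSCC", 0.9476, 0.9600, 0.9538, 0.9683),
    ("EfficientNet-B0 + LBP + XGBoost", "LACA", 0.9394, 0.9620, 0.9505, 0.9667),
    ("EfficientNet-B0 + LBP + XGBoost", "benign", 1.0, 0.9990, 0.9995, 0.9667),
    ("EfficientNet-B0 + LBP + XGBoost", "LSCC", 0.9611, 0.9390, 0.9499, 0.9667),
    ("EfficientNet-B0 + LBP + ViT Encoder + LR", "LACA", 0.9979, 0.9970, 0.9974, 0.9983),
    ("EfficientNet-B0 + LBP + ViT Encoder + LR", "benign", 1.0, 1.0, 1.0, 0.9983),
    ("EfficientNet-B0 + LBP + ViT Encoder + LR", "LSCC", 0.9970, 0.9980, 0.9975, 0.9983),
    ("EfficientNet-B0 + LBP + ViT Encoder + SVM", "LACA", 0.9989, 0.9970, 0.9979, 0.9987),
    ("EfficientNet-B0 + LBP + ViT Encoder + SVM", "benign", 1.0, 1.0, 1.0, 0.9987),
    ("EfficientNet-B0 + LBP + ViT Encoder + SVM", "LSCC", 0.9970, 0.9990, 0.9980, 0.9987),
    ("EfficientNet-B0 + LBP + ViT Encoder + LGBM", "LACA", 0.9929, 0.9910, 0.9919, 0.9947),
    ("EfficientNet-B0 + LBP + ViT Encoder + LGBM", "benign", 0.9960, 1.0, 0.9980, 0.9947),
    ("EfficientNet-B0 + LBP + ViT Encoder + LGBM", "LSCC", 0.9949, 0.9930, 0.9939, 0.9947),
    ("EfficientNet-B0 + LBP + ViT Encoder + XGBoost", "LACA", 0.9940, 0.9950, 0.9945, 0.9963),
    ("EfficientNet-B0 + LBP + ViT Encoder + XGBoost", "benign", 0.9980, 0.9990, 0.9985, 0.9963),
    ("EfficientNet-B0 + LBP + ViT Encoder + XGBoost", "LSCC", 0.9969, 0.9950, 0.9959, 0.9963),
]

#: Scenario using the full fused feature set with the SVM classifier.
BEST_METHOD = "EfficientNet-B0 + LBP + ViT Encoder + SVM"


def benchmark_table() -> pd.DataFrame:
    """Reference benchmark metrics as a tidy DataFrame."""
    return pd.DataFrame(
        _ROWS,
        columns=["method", "class", "precision", "recall", "f1", "accuracy"],
    )
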