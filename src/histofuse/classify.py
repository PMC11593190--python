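"""Classical classifiers on fused feature matrices.

Four families are supported: ``max_margin`` (RBF-kernel SVM), ``logistic_
regression`` (L2-penalised), and two gradient-boosted tree variants —
``boosted_trees_A`` (leaf-wise growth, LightGBM) and ``boosted_trees_B``
(level-wise growth, XGBoost).  SVM and logistic regression are trained
one-vs-rest, matching the per-class evaluation protocol; the tree
ensembles use their native multiclass objectives.

Standardisation (per-feature z-score with train statistics, zero-variance
features mapped to 0) is applied by default for the margin-based and
linear models and skipped for trees, which are scale-invariant.  All
defaults are overridable through ``ClassifierSpec.hyperparameters`` and
recorded in the run manifest.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC

from .fusion_matrix import FeatureMatrix

ALGORITHMS = (
    "max_margin",
    "logistic_regression",
    "boosted_trees_A",
    "boosted_trees_B",
)

#: Algorithms standardised by default.
_STANDARDIZE_DEFAULT = {
    "max_margin": True,
    "logistic_regression": True,
    "boosted_trees_A": False,
    "boosted_trees_B": False,
}


@dataclass
class ClassifierSpec:
    """Algorithm choice, hyperparameter overrides and seed."""

    algorithm: str = "max_margin"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0
    standardize: bool | None = None  # None -> per-algorithm default

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}"
            )

    @property
    def effective_standardize(self) -> bool:
        if self.standardize is None:
            return _STANDARDIZE_DEFAULT[self.algorithm]
        return self.standardize


@dataclass
class StandardizeStats:
    """Per-feature train mean and population standard deviation."""

    mean: np.ndarray
    sd: np.ndarray


@dataclass
class TrainedModel:
    """Fitted estimator plus the preprocessing needed to apply it."""

    algorithm: str
    estimator: object
    stats: StandardizeStats | None
    classes: np.ndarray
    n_features: int


def standardize_fit_apply(X: np.ndarray) -> tuple[StandardizeStats, np.ndarray]:
    """Fit per-feature z-score statistics on X and apply them.

    Uses the population standard deviation (ddof=0); zero-variance
    features transform to exactly 0.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("standardisation needs a 2-D matrix with n >= 2")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    stats = StandardizeStats(mean=mean, sd=sd)
    return stats, apply_standardization(stats, X)


def apply_standardization(stats: StandardizeStats, X: np.ndarray) -> np.ndarray:
    """Apply stored train statistics to any matrix of matching width."""
    X = np.asarray(X, dtype=np.float64)
    safe_sd = np.where(stats.sd == 0.0, 1.0, stats.sd)
    Z = (X - stats.mean) / safe_sd
    Z[:, stats.sd == 0.0] = 0.0
    return Z


def _build_estimator(spec: ClassifierSpec):
    hp = dict(spec.hyperparameters)
    if spec.algorithm == "max_margin":
        base = SVC(kernel="rbf", C=1.0, random_state=spec.seed, **hp)
        return OneVsRestClassifier(base)
    if spec.algorithm == "logistic_regression":
        # L2 penalty (sklearn's default; the explicit kwarg is deprecated)
        base = LogisticRegression(C=1.0, max_iter=2000,
                                  random_state=spec.seed, **hp)
        return OneVsRestClassifier(base)
    if spec.algorithm == "boosted_trees_A":
        from lightgbm import LGBMClassifier
        params = dict(n_estimators=100, max_depth=8, num_leaves=31,
                      random_state=spec.seed, n_jobs=1, deterministic=True,
                      force_row_wise=True, verbose=-1)
        params.update(hp)
        return LGBMClassifier(**params)
    if spec.algorithm == "boosted_trees_B":
        from xgboost import XGBClassifier
        params = dict(n_estimators=100, max_depth=6, random_state=spec.seed,
                      n_jobs=1, tree_method="hist", verbosity=0)
        params.update(hp)
        return XGBClassifier(**params)
    raise ValueError(spec.algorithm)


def train_classifier(matrix: FeatureMatrix | np.ndarray,
                     spec: ClassifierSpec,
                     labels=None) -> TrainedModel:
    """Fit a classifier on a feature matrix.

    Deterministic given (matrix, spec, seed).  Accepts either a
    :class:`FeatureMatrix` or a bare (X, labels) pair.
    """
    if isinstance(matrix, FeatureMatrix):
        X, y = matrix.X, matrix.labels
    else:
        X, y = np.asarray(matrix, dtype=np.float64), np.asarray(labels)
    if X.shape[0] < 4:
        raise ValueError("training needs at least 4 samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("training features contain NaN or infinite values")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training needs at least 2 classes")

    stats = None
    if spec.effective_standardize:
        stats, X = standardize_fit_apply(X)

    est = _build_estimator(spec)
    est.fit(X, y)
    return TrainedModel(algorithm=spec.algorithm, estimator=est,
                        stats=stats, classes=classes,
                        n_features=X.shape[1])


def predict(model: TrainedModel,
            matrix: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Predict class codes, applying the model's stored standardisation."""
    X = matrix.X if isinstance(matrix, FeatureMatrix) else np.asarray(matrix)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"feature width {X.shape[1] if X.ndim == 2 else '?'} does not "
            f"match training width {model.n_features}"
        )
    if model.stats is not None:
        X = apply_standardization(model.stats, X)
    return np.asarray(model.estimator.predict(X))
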