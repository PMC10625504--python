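"""Leakage-safe standardization, SVM training/prediction, and the
universal velocity-threshold baseline.

The Z-transformation is fit on training columns only and the same
transformation is applied to test columns — test-block means are in
general nonzero, which is exactly the leakage-safety contract.  The SVM is
a standard soft-margin classifier (RBF kernel, C = 1, kernel scale
1/(n_features * feature variance), i.e. the mainstream library defaults).

The baseline classifier is a single cut on per-trial maximum vertical
object velocity, chosen by exhaustive search over midpoints of sorted
adjacent training values (optimal for one cut); it is the non-learning
reference the SVM must beat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

__all__ = [
    "SVMConfig",
    "StandardizationParams",
    "TrainedClassifier",
    "ThresholdResult",
    "DegenerateVarianceError",
    "TrainingError",
    "zscore_fit",
    "zscore_apply",
    "train_svm",
    "predict",
    "threshold_baseline",
]

logger = logging.getLogger(__name__)

_ZERO_VAR_TOL = 1e-12


class DegenerateVarianceError(ValueError):
    """Standardization needs at least two training columns."""


class TrainingError(ValueError):
    """SVM training requires both classes."""


@dataclass(frozen=True)
class SVMConfig:
    kernel: str = "rbf"
    C: float = 1.0
    gamma: str | float = "scale"


@dataclass
class StandardizationParams:
    """Per-feature (row) mean/SD estimated from training columns only.

    Zero-variance features are flagged and only centered (SD treated as 1);
    they are kept so the feature dimension nN never changes silently.
    """

    mean: np.ndarray
    sd: np.ndarray
    zero_variance: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))


@dataclass
class TrainedClassifier:
    model: SVC
    hyper: SVMConfig
    seed: int
    n_features: int


def zscore_fit(X_train: np.ndarray) -> StandardizationParams:
    """Fit the Z-transformation on a training block (features x trials)."""
    X_train = np.asarray(X_train, dtype=float)
    if X_train.ndim != 2:
        raise ValueError("expected a 2-D feature block (features x trials)")
    if X_train.shape[1] < 2:
        raise DegenerateVarianceError(
            "need at least 2 training columns to estimate a variance"
        )
    mean = X_train.mean(axis=1)
    sd = X_train.std(axis=1, ddof=1)
    zero = sd <= _ZERO_VAR_TOL
    if zero.any():
        logger.warning(
            "%d zero-variance feature(s); centering only", int(zero.sum())
        )
    sd = np.where(zero, 1.0, sd)
    return StandardizationParams(mean=mean, sd=sd, zero_variance=zero)


def zscore_apply(params: StandardizationParams, X: np.ndarray) -> np.ndarray:
    """Apply training-fitted standardization to any block (train or test)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] != len(params.mean):
        raise ValueError(
            f"feature dimension {X.shape[0]} != fitted dimension {len(params.mean)}"
        )
    return (X - params.mean[:, None]) / params.sd[:, None]


def train_svm(
    X: np.ndarray,
    y: np.ndarray,
    hyper: SVMConfig | None = None,
    seed: int = 0,
) -> TrainedClassifier:
    """Fit the SVM on a standardized block (features x trials), labels ±1."""
    hyper = hyper or SVMConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise TrainingError("training labels contain a single class")
    model = SVC(kernel=hyper.kernel, C=hyper.C, gamma=hyper.gamma,
                random_state=seed)
    model.fit(X.T, y)
    return TrainedClassifier(model=model, hyper=hyper, seed=seed,
                             n_features=X.shape[0])


def predict(model: TrainedClassifier, X: np.ndarray) -> np.ndarray:
    """Predict ±1 labels for a standardized block (features x trials)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[0]} != training dimension {model.n_features}"
        )
    if X.shape[1] == 0:
        return np.empty(0, dtype=int)
    return model.model.predict(X.T).astype(int)


@dataclass
class ThresholdResult:
    cut: float
    light_above: bool                  # light predicted for values above the cut
    train_accuracy: float
    test_accuracy: float
    degenerate: bool = False


def _cut_accuracy(values, y, cut, light_above):
    pred = np.where(values > cut, -1, +1) if light_above else np.where(values > cut, +1, -1)
    return float(np.mean(pred == y))


def threshold_baseline(
    max_vertical_velocity: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
) -> ThresholdResult:
    """Universal single-cut classifier on peak vertical object velocity.

    The cut and its orientation (light above or below) are chosen to
    maximize training accuracy by exhaustive search over midpoints of
    sorted adjacent training values; returns the test accuracy.
    """
    v = np.asarray(max_vertical_velocity, dtype=float)
    y = np.asarray(y, dtype=int)
    v_tr, y_tr = v[train_idx], y[train_idx]
    if len(np.unique(y_tr)) < 2:
        raise TrainingError("training split contains a single class")
    uniq = np.unique(v_tr)
    if len(uniq) == 1:
        logger.warning("degenerate baseline: all training values equal")
        majority = int(np.sign(np.sum(y_tr)) or 1)
        acc = float(np.mean(y[test_idx] == majority))
        return ThresholdResult(cut=float(uniq[0]), light_above=True,
                               train_accuracy=max(np.mean(y_tr == majority), 0.0),
                               test_accuracy=acc, degenerate=True)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    cuts = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    best = (-1.0, 0.0, True)
    for cut in cuts:
        for light_above in (True, False):
            acc = _cut_accuracy(v_tr, y_tr, cut, light_above)
            if acc > best[0]:
                best = (acc, float(cut), light_above)
    train_acc, cut, light_above = best
    return ThresholdResult(
        cut=cut,
        light_above=light_above,
        train_accuracy=train_acc,
        test_accuracy=_cut_accuracy(v[test_idx], y[test_idx], cut, light_above),
    )
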