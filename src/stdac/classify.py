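"""Branch classifiers and spatial-temporal score fusion.

Two branch classifiers are trained on FBN features of spatially and
temporally augmented samples respectively. At prediction time a subject's
original (unaugmented) FBN features are scored by both branches, and the two
per-class probability vectors are fused by an outer (tensor) product:

    omega = f(s_spatial s_temporal^T),  flattened row-major (spatial-major)

where f de-means and scales the c*c entries to unit standard deviation.
Unlike concatenation, the outer product keeps every pairwise interaction of
branch scores (it is rank-1: reshaped, it equals s_spatial s_temporal^T
exactly). The fused vector feeds a third classifier that issues the final
label.

Branch scores are class probabilities for every classifier kind — the outer
product needs both vectors on a shared nonnegative scale, which raw margins
would not give. Supported kinds: linear-kernel SVM with Platt-calibrated
probabilities, a 500-tree random forest, and a one-hidden-layer (100-unit)
feed-forward neural network; multiclass is handled natively by each (the
linear SVM one-vs-rest).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import LinearSVC

from .fbn import pearson_fbn
from .io_data import SubjectTimeSeries

logger = logging.getLogger("stdac")

CLASSIFIER_KINDS = ("svm", "rf", "ann")

__all__ = [
    "CLASSIFIER_KINDS",
    "BranchModel",
    "STDACModel",
    "train_branch",
    "predict_scores",
    "fuse_scores",
    "fuse_score_matrix",
    "train_fusion",
    "fit_stdac",
    "stdac_predict",
]


@dataclass
class BranchModel:
    """A fitted classifier plus its fixed class order."""

    kind: str
    estimator: object
    classes: list

    @property
    def n_classes(self) -> int:
        return len(self.classes)


def _make_estimator(kind: str, seed: int, **hyper):
    if kind == "svm":
        base = LinearSVC(
            C=hyper.get("C", 1.0),
            random_state=seed,
            max_iter=hyper.get("max_iter", 5000),
        )
        return CalibratedClassifierCV(base, method="sigmoid", cv=3)
    if kind == "rf":
        return RandomForestClassifier(
            n_estimators=hyper.get("n_estimators", 500),
            random_state=seed,
            n_jobs=1,
        )
    if kind == "ann":
        return MLPClassifier(
            hidden_layer_sizes=hyper.get("hidden_layer_sizes", (100,)),
            random_state=seed,
            max_iter=hyper.get("max_iter", 500),
        )
    raise ValueError(f"unknown classifier kind {kind!r}; choose from {CLASSIFIER_KINDS}")


def train_branch(
    features: np.ndarray,
    labels: Sequence,
    kind: str = "svm",
    seed: int = 0,
    **hyper,
) -> BranchModel:
    """Fit one branch classifier on feature vectors (rows) and labels."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2:
        raise ValueError(f"features must be 2-D, got shape {X.shape}")
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"{X.shape[0]} feature rows but {y.shape[0]} labels")
    if np.unique(y).size < 2:
        raise ValueError("training set contains a single class; need >= 2")
    est = _make_estimator(kind, seed, **hyper)
    est.fit(X, y)
    return BranchModel(kind=kind, estimator=est, classes=list(est.classes_))


def predict_scores(model: BranchModel, features: np.ndarray) -> np.ndarray:
    """Per-class probability vectors, one row per sample, in model.classes order."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    n_expected = getattr(model.estimator, "n_features_in_", X.shape[1])
    if X.shape[1] != n_expected:
        raise ValueError(
            f"feature dimensionality {X.shape[1]} does not match the trained "
            f"model ({n_expected})"
        )
    return model.estimator.predict_proba(X)


def fuse_scores(s_spatial: np.ndarray, s_temporal: np.ndarray) -> np.ndarray:
    """Tensor-fuse one score pair into the normalized omega vector (length c*c).

    The outer product s_spatial s_temporal^T is flattened row-major (spatial
    index major) and z-scored across its c*c entries. A zero-variance product
    (both branches degenerate) yields the all-zero vector rather than an
    error, with a log note.
    """
    sp = np.asarray(s_spatial, dtype=float).ravel()
    te = np.asarray(s_temporal, dtype=float).ravel()
    if sp.size != te.size:
        raise ValueError(f"score lengths differ: {sp.size} vs {te.size}")
    if not (np.isfinite(sp).all() and np.isfinite(te).all()):
        raise ValueError("non-finite branch scores")
    omega = np.outer(sp, te).ravel()
    sd = omega.std()
    if sd == 0:
        logger.warning("degenerate fused score (zero variance); emitting zeros")
        return np.zeros_like(omega)
    return (omega - omega.mean()) / sd


def fuse_score_matrix(S_spatial: np.ndarray, S_temporal: np.ndarray) -> np.ndarray:
    """Row-wise fuse_scores for matrices of score vectors (n x c -> n x c*c)."""
    S_spatial = np.atleast_2d(S_spatial)
    S_temporal = np.atleast_2d(S_temporal)
    return np.vstack(
        [fuse_scores(sp, te) for sp, te in zip(S_spatial, S_temporal, strict=True)]
    )


def train_fusion(
    fused: np.ndarray, labels: Sequence, kind: str = "svm", seed: int = 0, **hyper
) -> BranchModel:
    """Fit the final classifier on fused omega vectors (length c*c each)."""
    return train_branch(fused, labels, kind=kind, seed=seed, **hyper)


@dataclass
class STDACModel:
    """The trained triple: spatial branch, temporal branch, fusion classifier."""

    spatial: BranchModel
    temporal: BranchModel
    fusion: BranchModel

    @property
    def classes(self) -> list:
        return self.fusion.classes


def fit_stdac(
    spatial_features: np.ndarray,
    spatial_labels: Sequence,
    temporal_features: np.ndarray,
    temporal_labels: Sequence,
    original_features: np.ndarray,
    original_labels: Sequence,
    kind: str = "svm",
    seed: int = 0,
    **hyper,
) -> STDACModel:
    """Train the full scheme.

    Branch classifiers learn from their augmented sets; the fusion classifier
    learns from the fused scores both branches assign to the ORIGINAL training
    subjects — mirroring the test-time contract, where only original samples
    are scored.
    """
    spatial = train_branch(spatial_features, spatial_labels, kind, seed, **hyper)
    temporal = train_branch(temporal_features, temporal_labels, kind, seed, **hyper)
    if list(spatial.classes) != list(temporal.classes):
        raise ValueError("branch class orders differ; inconsistent label sets")
    fused = fuse_score_matrix(
        predict_scores(spatial, original_features),
        predict_scores(temporal, original_features),
    )
    fusion = train_fusion(fused, original_labels, kind=kind, seed=seed, **hyper)
    return STDACModel(spatial=spatial, temporal=temporal, fusion=fusion)


def stdac_predict(model: STDACModel, subject: SubjectTimeSeries):
    """Classify one unaugmented subject end to end.

    Computes the subject's original-sample FBN features once, scores them with
    both branches, fuses, and returns ``(label, score_vector)`` from the
    fusion classifier (scores in ``model.classes`` order).
    """
    features = pearson_fbn(subject.signals).features[None, :]
    omega = fuse_score_matrix(
        predict_scores(model.spatial, features),
        predict_scores(model.temporal, features),
    )
    scores = predict_scores(model.fusion, omega)[0]
    label = model.classes[int(np.argmax(scores))]
    return label, scores
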