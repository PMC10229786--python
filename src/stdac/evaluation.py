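"""Leakage-safe stratified cross-validation of the four schemes.

Schemes (ablation arms):

- ``original``: one classifier on unaugmented FBN features.
- ``sda``: classifier trained on spatially augmented training samples only.
- ``tda``: classifier trained on temporally augmented training samples only.
- ``stdac``: both branches plus the tensor-fusion classifier.

Augmentation is applied strictly inside each training fold; test subjects are
always evaluated as originals. Every training sample's provenance is checked
against the test fold's subject ids before any model is fitted — a training
sample descending from a test subject raises :class:`LeakageError`.

Within a fold the SDA classifier IS the spatial branch of STDAC and the TDA
classifier IS the temporal branch (identical training data, seed and kind),
so each branch is fitted once and shared across schemes.

Metrics: Accuracy (%), per-class Precision and Recall (%), macro Precision,
and — for binary tasks — a pooled ROC curve with trapezoidal AUC. All
randomness (fold assignment, temporal draws, classifier seeds) derives from
one master seed recorded in the result.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import precision_score, recall_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .classify import (
    BranchModel,
    fuse_score_matrix,
    predict_scores,
    train_branch,
    train_fusion,
)
from .fbn import pearson_fbn
from .io_data import AtlasGeometry, SubjectTimeSeries
from .spatial import SpatialConfig, generate_spatial_set
from .temporal import TemporalConfig, generate_temporal_set

logger = logging.getLogger("stdac")

SCHEMES = ("original", "sda", "tda", "stdac")

__all__ = [
    "SCHEMES",
    "CVConfig",
    "CVResult",
    "LeakageError",
    "stratified_folds",
    "compute_metrics",
    "run_cv",
    "run_cv_schemes",
]


class LeakageError(RuntimeError):
    """A training sample's provenance traces to a test-fold subject."""


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation settings: folds, classifier kind, augmentation, seed."""

    n_folds: int = 10
    classifier: str = "svm"
    spatial: SpatialConfig = field(default_factory=SpatialConfig)
    temporal: TemporalConfig = field(default_factory=TemporalConfig)
    seed: int = 0
    hyper: dict = field(default_factory=dict)


@dataclass
class CVResult:
    """Per-fold and averaged metrics for one scheme."""

    scheme: str
    classes: list
    fold_accuracy: list[float]
    accuracy: float
    precision: dict
    recall: dict
    macro_precision: float
    y_true: list
    y_pred: list
    scores: np.ndarray  # pooled per-class score vectors, test subjects x c
    auc: float | None = None
    roc: dict | None = None
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "scheme": self.scheme,
            "classes": [str(c) for c in self.classes],
            "fold_accuracy": self.fold_accuracy,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "macro_precision": self.macro_precision,
            "auc": self.auc,
            "config": self.config,
        }
        if self.roc is not None:
            out["roc"] = self.roc
        return out


def stratified_folds(
    labels: Sequence, n_folds: int, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic stratified folds: disjoint, covering, class-balanced."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    too_small = classes[counts < n_folds]
    if too_small.size:
        raise ValueError(
            f"class(es) {too_small.tolist()} have fewer than n_folds={n_folds} "
            "members; reduce the fold count or merge/extend the cohort"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [(train, test) for train, test in skf.split(np.zeros(len(y)), y)]


def compute_metrics(
    y_true: Sequence,
    y_pred: Sequence,
    classes: Sequence,
    scores: np.ndarray | None = None,
) -> dict:
    """Accuracy and per-class Precision/Recall in percent; binary ROC if scored.

    Precision for a class nobody was assigned to is reported as 0 (logged).
    For binary tasks with per-class scores, the ROC treats ``classes[1]`` as
    the positive class and the AUC is the trapezoidal area under it.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("true and predicted label lists differ in length")
    classes = list(classes)
    accuracy = 100.0 * float(np.mean(y_true == y_pred))
    prec = precision_score(
        y_true, y_pred, labels=classes, average=None, zero_division=0
    )
    if np.any(prec == 0) and not set(classes) <= set(y_pred):
        logger.info("precision reported as 0 for class(es) never predicted")
    rec = recall_score(y_true, y_pred, labels=classes, average=None, zero_division=0)
    out = {
        "accuracy": accuracy,
        "precision": {str(c): 100.0 * p for c, p in zip(classes, prec)},
        "recall": {str(c): 100.0 * r for c, r in zip(classes, rec)},
        "macro_precision": 100.0 * float(np.mean(prec)),
    }
    if scores is not None and len(classes) == 2:
        pos = classes[1]
        fpr, tpr, thr = roc_curve(
            y_true, np.asarray(scores)[:, 1], pos_label=pos
        )
        out["roc"] = {
            "fpr": fpr.tolist(),
            "tpr": tpr.tolist(),
            "thresholds": thr.tolist(),
            "positive_class": str(pos),
        }
        out["auc"] = float(_trapezoid_auc(fpr, tpr))
    return out


def _fold_seed(master: int, fold: int) -> int:
    """A derived 31-bit stream seed, decorrelated across folds."""
    return int(np.random.SeedSequence([master, fold]).generate_state(1)[0] & 0x7FFFFFFF)


def _assert_no_leakage(samples: Sequence[SubjectTimeSeries], test_ids: set) -> None:
    for s in samples:
        src = getattr(s, "source_subject_id", "") or s.subject_id
        if src in test_ids:
            raise LeakageError(
                f"training sample {s.subject_id!r} derives from test subject "
                f"{src!r}; augmentation must not cross the fold boundary"
            )


def _features_of(samples: Sequence[SubjectTimeSeries]) -> np.ndarray:
    return np.vstack([pearson_fbn(s.signals).features for s in samples])


def run_cv_schemes(
    subjects: list[SubjectTimeSeries],
    geometry: AtlasGeometry,
    config: CVConfig,
    schemes: Sequence[str] = SCHEMES,
    fold_transform: Callable | None = None,
) -> dict[str, CVResult]:
    """Cross-validate several schemes on shared folds and shared branch fits.

    ``fold_transform(samples, fold_index)``, if given, may replace each fold's
    augmented-sample lists before the leakage check runs — an injection point
    for experimentation and for exercising the leakage sentinel.
    """
    unknown = set(schemes) - set(SCHEMES)
    if unknown:
        raise ValueError(f"unknown scheme(s) {sorted(unknown)}; choose from {SCHEMES}")
    labels = [s.label for s in subjects]
    classes = sorted(set(labels))
    folds = stratified_folds(labels, config.n_folds, seed=config.seed)

    need_spatial = {"sda", "stdac"} & set(schemes)
    need_temporal = {"tda", "stdac"} & set(schemes)
    per_scheme: dict[str, dict] = {
        s: {"fold_acc": [], "y_true": [], "y_pred": [], "scores": []} for s in schemes
    }

    for fold_i, (train_idx, test_idx) in enumerate(folds):
        train = [subjects[i] for i in train_idx]
        test = [subjects[i] for i in test_idx]
        test_ids = {s.subject_id for s in test}
        seed = _fold_seed(config.seed, fold_i)

        train_feats = _features_of(train)
        train_labels = [s.label for s in train]
        test_feats = _features_of(test)
        test_labels = [s.label for s in test]

        spatial_set = (
            generate_spatial_set(train, geometry, config.spatial)
            if need_spatial
            else []
        )
        temporal_set = (
            generate_temporal_set(
                train, dataclasses.replace(config.temporal, seed=seed)
            )
            if need_temporal
            else []
        )
        if fold_transform is not None:
            spatial_set = fold_transform(spatial_set, fold_i)
            temporal_set = fold_transform(temporal_set, fold_i)
        _assert_no_leakage([*train, *spatial_set, *temporal_set], test_ids)

        spatial_branch: BranchModel | None = None
        temporal_branch: BranchModel | None = None
        if need_spatial:
            spatial_branch = train_branch(
                _features_of(spatial_set),
                [s.label for s in spatial_set],
                kind=config.classifier,
                seed=seed,
                **config.hyper,
            )
        if need_temporal:
            temporal_branch = train_branch(
                _features_of(temporal_set),
                [s.label for s in temporal_set],
                kind=config.classifier,
                seed=seed,
                **config.hyper,
            )

        for scheme in schemes:
            if scheme == "original":
                model = train_branch(
                    train_feats, train_labels, config.classifier, seed, **config.hyper
                )
                scores = predict_scores(model, test_feats)
                model_classes = model.classes
            elif scheme == "sda":
                scores = predict_scores(spatial_branch, test_feats)
                model_classes = spatial_branch.classes
            elif scheme == "tda":
                scores = predict_scores(temporal_branch, test_feats)
                model_classes = temporal_branch.classes
            else:  # stdac
                fused_train = fuse_score_matrix(
                    predict_scores(spatial_branch, train_feats),
                    predict_scores(temporal_branch, train_feats),
                )
                fusion = train_fusion(
                    fused_train, train_labels, config.classifier, seed, **config.hyper
                )
                fused_test = fuse_score_matrix(
                    predict_scores(spatial_branch, test_feats),
                    predict_scores(temporal_branch, test_feats),
                )
                scores = predict_scores(fusion, fused_test)
                model_classes = fusion.classes
            preds = [model_classes[int(i)] for i in np.argmax(scores, axis=1)]
            acc = 100.0 * float(np.mean(np.asarray(preds) == np.asarray(test_labels)))
            bucket = per_scheme[scheme]
            bucket["fold_acc"].append(acc)
            bucket["y_true"].extend(test_labels)
            bucket["y_pred"].extend(preds)
            # reorder scores into the global sorted class order
            order = [model_classes.index(c) for c in classes]
            bucket["scores"].append(np.asarray(scores)[:, order])

    results: dict[str, CVResult] = {}
    cfg_snapshot = {
        "n_folds": config.n_folds,
        "classifier": config.classifier,
        "spatial_degree": config.spatial.degree,
        "spatial_r": config.spatial.r,
        "temporal_degree": config.temporal.degree,
        "l_frac": config.temporal.l_frac,
        "l_min_frac": config.temporal.l_min_frac,
        "seed": config.seed,
    }
    for scheme in schemes:
        b = per_scheme[scheme]
        pooled_scores = np.vstack(b["scores"])
        metrics = compute_metrics(b["y_true"], b["y_pred"], classes, pooled_scores)
        results[scheme] = CVResult(
            scheme=scheme,
            classes=classes,
            fold_accuracy=b["fold_acc"],
            accuracy=float(np.mean(b["fold_acc"])),
            precision=metrics["precision"],
            recall=metrics["recall"],
            macro_precision=metrics["macro_precision"],
            y_true=b["y_true"],
            y_pred=b["y_pred"],
            scores=pooled_scores,
            auc=metrics.get("auc"),
            roc=metrics.get("roc"),
            config=dict(cfg_snapshot, scheme=scheme),
        )
    return results


def run_cv(
    subjects: list[SubjectTimeSeries],
    geometry: AtlasGeometry,
    scheme: str,
    config: CVConfig,
    fold_transform: Callable | None = None,
) -> CVResult:
    """Cross-validate a single scheme (see :func:`run_cv_schemes`)."""
    return run_cv_schemes(
        subjects, geometry, config, schemes=[scheme], fold_transform=fold_transform
    )[scheme]
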