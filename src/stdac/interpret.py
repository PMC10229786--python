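"""Discriminative-connection and ROI ranking from trained branch classifiers.

Each trained classifier assigns an importance to every FBN edge feature:
absolute linear coefficients for the linear SVM (averaged over the
calibration folds and, for multiclass, over the one-vs-rest rows), Gini
impurity importances for the random forest, and input-layer weight magnitudes
summed over hidden units for the neural network. Importances from several
trained models (e.g. the per-fold models of a cross-validation) are averaged,
min-max normalized to [0, 1], and ranked; an ROI's weight is the sum of the
normalized weights of its incident edges (each edge counts at both
endpoints), so sum(roi_weights) = 2 * sum(edge_weights) exactly.

Exports: ranked edge TSV, ROI weight TSV, and BrainNet-Viewer ``.node`` /
``.edge`` files for glass-brain visualization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier

from .classify import BranchModel
from .fbn import devectorize, n_edges
from .io_data import AtlasGeometry

__all__ = [
    "EdgeWeightMap",
    "edge_weights",
    "aggregate_and_rank",
    "write_edge_ranking",
    "write_roi_weights",
    "write_brainnet_files",
]


@dataclass
class EdgeWeightMap:
    """Normalized edge weights (length m(m-1)/2) and accumulated ROI weights."""

    weights: np.ndarray
    roi_weights: np.ndarray
    branch: str = ""

    @property
    def n_rois(self) -> int:
        return self.roi_weights.size


def edge_weights(model: BranchModel) -> np.ndarray:
    """Raw nonnegative per-edge importances from one trained model."""
    est = model.estimator
    if isinstance(est, CalibratedClassifierCV):
        coefs = [cc.estimator.coef_ for cc in est.calibrated_classifiers_]
        return np.mean([np.abs(c).mean(axis=0) for c in coefs], axis=0)
    if isinstance(est, RandomForestClassifier):
        return np.asarray(est.feature_importances_, dtype=float)
    if isinstance(est, MLPClassifier):
        return np.abs(est.coefs_[0]).sum(axis=1)
    if hasattr(est, "coef_"):
        return np.abs(np.atleast_2d(est.coef_)).mean(axis=0)
    raise ValueError(
        f"cannot extract edge weights from classifier kind {model.kind!r} "
        f"({type(est).__name__})"
    )


def _minmax(w: np.ndarray) -> np.ndarray:
    lo, hi = float(w.min()), float(w.max())
    if hi == lo:
        return np.ones_like(w) if hi > 0 else np.zeros_like(w)
    return (w - lo) / (hi - lo)


def aggregate_and_rank(
    weight_vectors: Sequence[np.ndarray],
    roi_names: Sequence[str],
    top_k: int = 20,
    branch: str = "",
) -> tuple[EdgeWeightMap, list[tuple[int, str, str, float]]]:
    """Average fold-wise importances, normalize, rank the top_k edges.

    Returns the :class:`EdgeWeightMap` and a ranked list of
    ``(rank, roi_a, roi_b, weight)`` tuples (rank starting at 1). Ties are
    broken by ascending edge index for a stable order.
    """
    vectors = [np.asarray(v, dtype=float) for v in weight_vectors]
    m = len(roi_names)
    expected = n_edges(m)
    for v in vectors:
        if v.shape != (expected,):
            raise ValueError(
                f"weight vector length {v.shape} does not match {m} ROIs "
                f"({expected} edges)"
            )
    if top_k > expected:
        raise ValueError(f"top_k={top_k} exceeds the {expected} available edges")
    mean_w = np.mean(vectors, axis=0)
    norm_w = _minmax(mean_w)
    adj = devectorize(norm_w, m)
    np.fill_diagonal(adj, 0.0)
    roi_w = adj.sum(axis=1)

    iu = np.stack(np.triu_indices(m, k=1), axis=1)
    order = np.lexsort((np.arange(expected), -norm_w))[:top_k]
    ranked = [
        (rank + 1, roi_names[iu[e, 0]], roi_names[iu[e, 1]], float(norm_w[e]))
        for rank, e in enumerate(order)
    ]
    return EdgeWeightMap(weights=norm_w, roi_weights=roi_w, branch=branch), ranked


def write_edge_ranking(path, ranked: list[tuple[int, str, str, float]]) -> None:
    with open(path, "w") as fh:
        fh.write("rank\troi_a\troi_b\tweight\n")
        for rank, a, b, w in ranked:
            fh.write(f"{rank}\t{a}\t{b}\t{w:.10g}\n")


def write_roi_weights(path, roi_names: Sequence[str], roi_weights: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("roi\tweight\n")
        for name, w in zip(roi_names, roi_weights):
            fh.write(f"{name}\t{w:.10g}\n")


def write_brainnet_files(
    node_path,
    edge_path,
    geometry: AtlasGeometry,
    edge_map: EdgeWeightMap,
    top_k: int = 20,
) -> None:
    """BrainNet Viewer exports: .node (centroid + ROI weight as size) and
    .edge (adjacency restricted to the top_k edges)."""
    m = geometry.n_rois
    with open(node_path, "w") as fh:
        for i in range(m):
            x, y, z = geometry.coords[i]
            fh.write(
                f"{x:.6g}\t{y:.6g}\t{z:.6g}\t1\t"
                f"{edge_map.roi_weights[i]:.6g}\t{geometry.roi_names[i]}\n"
            )
    adj = devectorize(edge_map.weights, m)
    np.fill_diagonal(adj, 0.0)
    iu = np.triu_indices(m, k=1)
    flat = adj[iu]
    keep = np.zeros_like(flat, dtype=bool)
    keep[np.lexsort((np.arange(flat.size), -flat))[:top_k]] = True
    flat = np.where(keep, flat, 0.0)
    top_adj = devectorize(flat, m)
    np.fill_diagonal(top_adj, 0.0)
    np.savetxt(edge_path, top_adj, delimiter="\t", fmt="%.6g")
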