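"""Spatial augmentation: neighbor-averaged ROI time series.

Brain regions that are close in space tend to carry similar signals, so a new
plausible sample can be made from a subject by replacing each node's time
series with the mean over a small spatially constrained neighbor set. For
node i the neighbor set C_i holds node i itself plus its k nearest nodes, but
only those strictly closer than a radius r*D, where D is the largest
centroid-to-centroid distance in the atlas and 0 < r < 1:

    |C_i| <= k + 1
    d(i, s) < d(i, j)   for every s in C_i, j not in C_i
    d(i, s) < r * D     for every neighbor s != i

The updated series is y_i = mean over C_i of the ORIGINAL columns (no
sequential in-place update), so column i is the element-wise average of up to
k+1 raw columns. Varying k = 1..degree yields `degree` distinct augmented
samples per subject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_data import AtlasGeometry, AugmentedSample, SubjectTimeSeries

__all__ = [
    "SpatialConfig",
    "NeighborSet",
    "build_neighbor_set",
    "spatial_augment_sample",
    "generate_spatial_set",
]


@dataclass(frozen=True)
class SpatialConfig:
    """Neighborhood parameters.

    k: number of nearest neighbors averaged into each node (0 = identity).
    r: radius as a fraction of the atlas diameter D, 0 < r < 1. The strict
       constraint d(i,s) < r*D caps how far a "neighbor" may be; 0.5 is the
       package default.
    degree: augmented samples generated per subject, realized as k = 1..degree.
    """

    k: int = 1
    r: float = 0.5
    degree: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.r < 1:
            raise ValueError(f"r must be in (0, 1), got {self.r}")
        if self.k < 0:
            raise ValueError(f"k must be nonnegative, got {self.k}")
        if self.degree < 1:
            raise ValueError(f"degree must be >= 1, got {self.degree}")


@dataclass(frozen=True)
class NeighborSet:
    """The spatially constrained neighbor set C_i of a center node."""

    center: int
    members: tuple[int, ...]  # sorted ascending; always contains center

    def __post_init__(self) -> None:
        if self.center not in self.members:
            raise ValueError("neighbor set must contain its center")


def build_neighbor_set(
    i: int, geometry: AtlasGeometry, cfg: SpatialConfig
) -> NeighborSet:
    """Neighbor set of node i: itself plus up to k nearest nodes within r*D.

    Candidates are sorted by (distance, node index) — ascending-index
    tie-break — and the first k inside the strict radius are kept; a nearer
    node is never excluded in favor of a farther one. The radius may
    legitimately leave the set at just {i}.
    """
    m = geometry.n_rois
    if not 0 <= i < m:
        raise ValueError(f"node index {i} out of range for {m} ROIs")
    radius = cfg.r * geometry.max_dist
    d = geometry.dist[i]
    candidates = [j for j in range(m) if j != i and d[j] < radius]
    candidates.sort(key=lambda j: (d[j], j))
    members = tuple(sorted([i] + candidates[: cfg.k]))
    return NeighborSet(center=i, members=members)


def spatial_augment_sample(
    subject: SubjectTimeSeries, geometry: AtlasGeometry, cfg: SpatialConfig
) -> AugmentedSample:
    """One neighbor-averaged sample: y_i = mean of original columns in C_i."""
    if subject.n_rois != geometry.n_rois:
        raise ValueError(
            f"subject {subject.subject_id!r} has {subject.n_rois} ROIs but "
            f"atlas has {geometry.n_rois}"
        )
    x = subject.signals
    y = np.empty_like(x)
    for i in range(geometry.n_rois):
        members = build_neighbor_set(i, geometry, cfg).members
        y[:, i] = x[:, members].mean(axis=1)
    return AugmentedSample(
        subject_id=f"{subject.subject_id}__spatial_k{cfg.k}",
        signals=y,
        label=subject.label,
        source_subject_id=subject.subject_id,
        provenance={"method": "spatial", "k": cfg.k, "r": cfg.r},
    )


def generate_spatial_set(
    subjects: list[SubjectTimeSeries],
    geometry: AtlasGeometry,
    cfg: SpatialConfig,
) -> list[AugmentedSample]:
    """`degree` augmented samples per subject, one for each k = 1..degree."""
    if subjects and cfg.degree > geometry.n_rois - 1:
        raise ValueError(
            f"spatial degree {cfg.degree} needs k up to {cfg.degree} but the "
            f"atlas has only {geometry.n_rois} ROIs (k <= m-1)"
        )
    out: list[AugmentedSample] = []
    for k in range(1, cfg.degree + 1):
        k_cfg = SpatialConfig(k=k, r=cfg.r, degree=cfg.degree)
        for subject in subjects:
            out.append(spatial_augment_sample(subject, geometry, k_cfg))
    return out
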