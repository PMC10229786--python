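"""Synthetic rs-fMRI cohorts with planted group-dependent connectivity.

Because Pearson correlation is the analysis target, second-order structure is
the sufficient statistic to emulate: each subject's t time points are drawn
i.i.d. from a zero-mean multivariate normal with a class-specific correlation
matrix, plus optional white measurement noise, then z-scored per ROI — the
same form as preprocessed ROI-level BOLD signals. Group differences are
"planted" as additive deltas on chosen edges of a smooth background
correlation matrix (rho^|i-j|), giving known discriminative connections for
parameter-recovery tests.

Atlas geometry is a jittered 3-D lattice, which gives realistic
nearest-neighbor structure for the spatial-augmentation module without any
real template. Defaults mirror the scale of a typical ROI-level cohort:
t = 137 time points, m = 30 regions (m = 116 matches the AAL template but is
slower), 20 subjects per class.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_data import (
    AtlasGeometry,
    SubjectTimeSeries,
    write_atlas,
    write_manifest,
    write_time_series,
    zscore_columns,
)

__all__ = [
    "SimulationSpec",
    "DEFAULT_PLANTED_EDGES",
    "make_geometry",
    "class_correlation",
    "simulate_cohort",
    "write_cohort",
]

# five discriminative edges, deltas 0.4-0.6 applied to the second class
DEFAULT_PLANTED_EDGES: tuple = (
    (0, 1, (0.0, 0.6)),
    (4, 5, (0.0, 0.5)),
    (9, 12, (0.0, 0.6)),
    (15, 20, (0.0, 0.4)),
    (22, 27, (0.0, 0.5)),
)


@dataclass(frozen=True)
class SimulationSpec:
    """Cohort-generator settings.

    n_per_class: subjects per class. m / t: ROIs and time points per subject.
    classes: ordered class labels. base_rho: background correlation decay
    (corr(i,j) = base_rho**|i-j|). planted_edges: (i, j, per-class deltas)
    added to the background for each class. noise_sd: white-noise sd added on
    top of the unit-variance latent signal. spacing / jitter: lattice step
    (mm) and jitter fraction for the synthetic atlas. seed: master seed.
    """

    n_per_class: int = 20
    m: int = 30
    t: int = 137
    classes: tuple = ("control", "patient")
    base_rho: float = 0.3
    planted_edges: tuple = DEFAULT_PLANTED_EDGES
    noise_sd: float = 0.25
    spacing: float = 10.0
    jitter: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1 or self.m < 2 or self.t < 3:
            raise ValueError("need n_per_class >= 1, m >= 2, t >= 3")
        if not 0 <= self.base_rho < 1:
            raise ValueError(f"base_rho must be in [0, 1), got {self.base_rho}")
        for i, j, deltas in self.planted_edges:
            if i == j:
                raise ValueError(f"planted edge ({i},{j}) has identical endpoints")
            if not (0 <= i < self.m and 0 <= j < self.m):
                raise ValueError(f"planted edge ({i},{j}) outside m={self.m} ROIs")
            if len(deltas) != len(self.classes):
                raise ValueError(
                    f"edge ({i},{j}): {len(deltas)} deltas for "
                    f"{len(self.classes)} classes"
                )

    def null(self) -> "SimulationSpec":
        """The same spec with no planted effect (identical class matrices)."""
        return dataclasses.replace(self, planted_edges=())


def make_geometry(m: int, spacing: float = 10.0, seed: int = 0, jitter: float = 0.1
                  ) -> AtlasGeometry:
    """m centroids on a jittered cubic lattice with the given step (mm)."""
    if m < 2:
        raise ValueError(f"need m >= 2 ROIs, got {m}")
    side = math.ceil(m ** (1 / 3))
    pts = [
        (x, y, z)
        for x in range(side)
        for y in range(side)
        for z in range(side)
    ][:m]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA71A5]))
    coords = np.asarray(pts, dtype=float) * spacing
    coords += rng.uniform(-jitter * spacing, jitter * spacing, size=coords.shape)
    names = [f"ROI_{i + 1:03d}" for i in range(m)]
    return AtlasGeometry(roi_names=names, coords=coords)


def class_correlation(spec: SimulationSpec, class_index: int) -> np.ndarray:
    """Target correlation matrix of one class; fatal if not positive definite."""
    idx = np.arange(spec.m)
    corr = spec.base_rho ** np.abs(idx[:, None] - idx[None, :])
    for i, j, deltas in spec.planted_edges:
        value = corr[i, j] + deltas[class_index]
        if not -1 < value < 1:
            raise ValueError(
                f"edge ({i},{j}) correlation {value} outside (-1, 1) for class "
                f"{spec.classes[class_index]!r}"
            )
        corr[i, j] = corr[j, i] = value
    try:
        np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"class {spec.classes[class_index]!r} correlation matrix is not "
            "positive definite; reduce deltas or base_rho"
        ) from exc
    return corr


def simulate_cohort(
    spec: SimulationSpec,
) -> tuple[list[SubjectTimeSeries], AtlasGeometry, dict]:
    """Draw a cohort: subjects, atlas geometry and the ground-truth record.

    Each subject's rows are i.i.d. N(0, Sigma_class); white noise of sd
    ``noise_sd`` is added and every ROI column is z-scored, so generated
    cohorts satisfy the loader's invariants without modification. Every
    subject's stream derives from SeedSequence([seed, class_index,
    subject_index]) and is independent of generation order.
    """
    geometry = make_geometry(spec.m, spec.spacing, spec.seed, spec.jitter)
    class_mats = [class_correlation(spec, ci) for ci in range(len(spec.classes))]
    subjects: list[SubjectTimeSeries] = []
    for ci, label in enumerate(spec.classes):
        chol = np.linalg.cholesky(class_mats[ci])
        for si in range(spec.n_per_class):
            rng = np.random.default_rng(
                np.random.SeedSequence([spec.seed, ci, si])
            )
            latent = rng.standard_normal((spec.t, spec.m)) @ chol.T
            if spec.noise_sd > 0:
                latent = latent + rng.normal(0.0, spec.noise_sd, latent.shape)
            sid = f"{label}_{si + 1:03d}"
            signals = zscore_columns(latent, name=f"subject {sid!r}")
            subjects.append(SubjectTimeSeries(sid, signals, label))
    ground_truth = {
        "classes": list(spec.classes),
        "planted_edges": [
            {"i": int(i), "j": int(j), "deltas": list(map(float, d))}
            for i, j, d in spec.planted_edges
        ],
        "base_rho": spec.base_rho,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
        "class_correlations": [mat.tolist() for mat in class_mats],
    }
    return subjects, geometry, ground_truth


def write_cohort(
    out_dir,
    subjects: list[SubjectTimeSeries],
    geometry: AtlasGeometry,
    ground_truth: dict | None = None,
) -> Path:
    """Write manifest.csv, atlas.csv, per-subject series and ground_truth.json."""
    out = Path(out_dir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    records = []
    for s in subjects:
        rel = f"timeseries/{s.subject_id}.tsv"
        write_time_series(out / rel, s.signals)
        records.append((s.subject_id, rel, s.label))
    write_manifest(out / "manifest.csv", records)
    write_atlas(out / "atlas.csv", geometry)
    if ground_truth is not None:
        (out / "ground_truth.json").write_text(json.dumps(ground_truth, indent=1))
    return out / "manifest.csv"
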