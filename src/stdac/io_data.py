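"""Cohort, time-series and atlas-geometry I/O.

The canonical in-memory objects are :class:`SubjectTimeSeries` (one subject's
t x m ROI signal matrix, rows = time points, columns = ROIs),
:class:`AtlasGeometry` (ROI names, 3-D centroids in mm, pairwise Euclidean
distances) and :class:`CohortManifest` (subject id, file path, class label).

On-disk formats are plain delimited text: the manifest is a CSV with columns
``subject_id,path,label``; the atlas is a CSV with columns ``roi_name,x,y,z``
(MNI mm) or a BrainNet-Viewer ``.node`` table (``x y z color size label``,
whitespace-delimited); each time-series file is a delimited numeric table with
an optional single header row (delimiter auto-detected).

ROI order is defined by the atlas file and every subject must conform to it;
node indices are 0-based throughout. By default each ROI column is z-scored at
load time (mean 0, unit sd); a constant column is an error because the signal
carries no information and breaks both z-scoring and Pearson correlation.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "SubjectTimeSeries",
    "AugmentedSample",
    "AtlasGeometry",
    "CohortManifest",
    "CohortError",
    "zscore_columns",
    "compute_distance_matrix",
    "load_time_series",
    "load_atlas",
    "load_manifest",
    "load_cohort",
    "write_time_series",
    "write_atlas",
    "write_manifest",
]


class CohortError(ValueError):
    """Raised for malformed cohorts: bad shapes, constant ROIs, unknown labels."""


@dataclass
class SubjectTimeSeries:
    """One subject's ROI signal matrix of shape (t, m) plus its class label."""

    subject_id: str
    signals: np.ndarray
    label: str

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise CohortError(
                f"subject {self.subject_id!r}: signals must be 2-D, "
                f"got ndim={self.signals.ndim}"
            )
        t, m = self.signals.shape
        if t < 2 or m < 2:
            raise CohortError(
                f"subject {self.subject_id!r}: need at least 2 time points and "
                f"2 ROIs, got shape {self.signals.shape}"
            )
        if not np.isfinite(self.signals).all():
            raise CohortError(f"subject {self.subject_id!r}: non-finite signal values")

    @property
    def n_timepoints(self) -> int:
        return self.signals.shape[0]

    @property
    def n_rois(self) -> int:
        return self.signals.shape[1]


@dataclass
class AugmentedSample(SubjectTimeSeries):
    """A derived time-series sample with provenance back to its source subject.

    ``provenance`` records the augmentation method and its parameters, e.g.
    ``{"method": "spatial", "k": 2}`` or ``{"method": "temporal",
    "indices": [...]}``. ``source_subject_id`` always names the original
    (unaugmented) subject so that cross-validation can verify that no training
    sample descends from a test subject.
    """

    source_subject_id: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        super().__post_init__()
        if not self.source_subject_id:
            raise CohortError("augmented sample requires a source_subject_id")


@dataclass
class AtlasGeometry:
    """ROI names, centroid coordinates (mm) and pairwise Euclidean distances."""

    roi_names: list[str]
    coords: np.ndarray
    dist: np.ndarray = field(init=False)
    max_dist: float = field(init=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise CohortError(f"atlas coords must be m x 3, got {self.coords.shape}")
        if len(self.roi_names) != self.coords.shape[0]:
            raise CohortError(
                f"{len(self.roi_names)} ROI names but {self.coords.shape[0]} centroids"
            )
        if len(set(self.roi_names)) != len(self.roi_names):
            raise CohortError("duplicate ROI names in atlas")
        self.dist, self.max_dist = compute_distance_matrix(self.coords)

    @property
    def n_rois(self) -> int:
        return self.coords.shape[0]


@dataclass
class CohortManifest:
    """Ordered subject records (id, path, label) and the ordered class labels."""

    records: list[tuple[str, str, str]]
    class_names: list[str]

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortError(f"duplicate subject ids in manifest: {dupes}")
        unknown = sorted({r[2] for r in self.records} - set(self.class_names))
        if unknown:
            raise CohortError(f"labels not in class_names: {unknown}")


def compute_distance_matrix(coords: np.ndarray) -> tuple[np.ndarray, float]:
    """Pairwise Euclidean distances between ROI centroids and their maximum.

    Returns ``(dist, max_dist)`` where ``dist`` is the symmetric m x m distance
    matrix with zero diagonal and ``max_dist`` is its largest entry (the atlas
    diameter D used by the spatial-neighborhood radius ``r * D``).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 2:
        raise CohortError(f"coords must be m x 3 with m >= 2, got {coords.shape}")
    if not np.isfinite(coords).all():
        raise CohortError("non-finite atlas coordinates")
    dist = squareform(pdist(coords, metric="euclidean"))
    return dist, float(dist.max())


def zscore_columns(signals: np.ndarray, name: str = "sample") -> np.ndarray:
    """Z-score each ROI column to mean 0, sd 1 (population sd, ddof=0).

    A constant column is fatal: the corresponding ROI would have an undefined
    correlation with every other node.
    """
    signals = np.asarray(signals, dtype=float)
    sd = signals.std(axis=0)
    const = np.flatnonzero(sd == 0)
    if const.size:
        raise CohortError(
            f"{name}: constant signal in ROI column(s) {const.tolist()}; "
            "cannot normalize"
        )
    return (signals - signals.mean(axis=0)) / sd


def _read_delimited(path: str | os.PathLike) -> np.ndarray:
    """Read a numeric table; auto-detect delimiter and an optional header row."""
    text = Path(path).read_text()
    first = text.lstrip().splitlines()[0] if text.strip() else ""
    delim = None  # python engine: any whitespace
    for cand in ("\t", ",", ";"):
        if cand in first:
            delim = cand
            break
    kwargs = dict(header=None, comment="#")
    if delim is None:
        kwargs["sep"] = r"\s+"  # python engine parses floats exactly
    else:
        kwargs["sep"] = delim
        kwargs["float_precision"] = "round_trip"
    df = pd.read_csv(io.StringIO(text), **kwargs)
    if df.iloc[0].map(lambda v: isinstance(v, str)).any():
        df = df.iloc[1:].reset_index(drop=True)  # single header row
    try:
        return df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise CohortError(f"{path}: non-numeric time-series table ({exc})") from exc


def load_time_series(path: str | os.PathLike) -> np.ndarray:
    """Load one subject's t x m signal matrix from delimited text."""
    arr = _read_delimited(path)
    if arr.ndim != 2:
        raise CohortError(f"{path}: expected a 2-D table")
    if not np.isfinite(arr).all():
        raise CohortError(f"{path}: missing or non-finite values")
    return arr


def load_atlas(path: str | os.PathLike) -> AtlasGeometry:
    """Load atlas geometry from CSV (roi_name,x,y,z) or BrainNet .node layout."""
    path = Path(path)
    if path.suffix.lower() == ".node":
        # BrainNet Viewer: x y z color size label, whitespace-delimited
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
        if df.shape[1] < 3:
            raise CohortError(f"{path}: .node file needs at least x y z columns")
        coords = df.iloc[:, :3].to_numpy(dtype=float)
        if df.shape[1] >= 6:
            names = [str(v) for v in df.iloc[:, 5]]
        else:
            names = [f"ROI_{i + 1:03d}" for i in range(len(df))]
        return AtlasGeometry(roi_names=names, coords=coords)

    df = pd.read_csv(path, comment="#")
    cols = [str(c).strip().lower() for c in df.columns]
    if {"roi_name", "x", "y", "z"}.issubset(cols):
        df.columns = cols
    else:  # headerless roi_name,x,y,z
        df = pd.read_csv(path, header=None, comment="#")
        if df.shape[1] < 4:
            raise CohortError(f"{path}: atlas CSV needs roi_name,x,y,z columns")
        df.columns = ["roi_name", "x", "y", "z"] + list(df.columns[4:])
    coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    return AtlasGeometry(roi_names=[str(n) for n in df["roi_name"]], coords=coords)


def load_manifest(path: str | os.PathLike) -> CohortManifest:
    """Load a cohort manifest CSV with columns subject_id,path,label."""
    df = pd.read_csv(path, dtype=str, comment="#")
    df.columns = [str(c).strip().lower() for c in df.columns]
    required = {"subject_id", "path", "label"}
    if not required.issubset(df.columns):
        raise CohortError(
            f"{path}: manifest must have columns subject_id,path,label, "
            f"got {list(df.columns)}"
        )
    records = list(zip(df["subject_id"], df["path"], df["label"]))
    class_names = list(dict.fromkeys(df["label"]))  # order of first appearance
    return CohortManifest(records=records, class_names=class_names)


def load_cohort(
    manifest_path: str | os.PathLike,
    atlas_path: str | os.PathLike,
    normalize: bool = True,
) -> tuple[list[SubjectTimeSeries], AtlasGeometry]:
    """Load a full cohort: per-subject ROI time series plus atlas geometry.

    Subjects are returned in manifest order, z-scored per ROI column unless
    ``normalize=False``. Relative time-series paths are resolved against the
    manifest's directory. Any subject whose column count differs from the
    atlas ROI count is fatal, naming the offending subject.
    """
    manifest = load_manifest(manifest_path)
    geometry = load_atlas(atlas_path)
    base = Path(manifest_path).parent
    subjects: list[SubjectTimeSeries] = []
    for subject_id, rel_path, label in manifest.records:
        ts_path = Path(rel_path)
        if not ts_path.is_absolute():
            ts_path = base / ts_path
        if not ts_path.exists():
            raise CohortError(f"subject {subject_id!r}: file not found: {ts_path}")
        signals = load_time_series(ts_path)
        if signals.shape[1] != geometry.n_rois:
            raise CohortError(
                f"subject {subject_id!r}: {signals.shape[1]} ROI columns but "
                f"atlas has {geometry.n_rois} ROIs"
            )
        if normalize:
            const = np.flatnonzero(signals.std(axis=0) == 0)
            if const.size:
                names = ", ".join(geometry.roi_names[i] for i in const)
                raise CohortError(
                    f"subject {subject_id!r}: constant signal in ROI(s) {names}"
                )
            signals = zscore_columns(signals, name=f"subject {subject_id!r}")
        subjects.append(SubjectTimeSeries(subject_id, signals, label))
    return subjects, geometry


def write_time_series(
    path: str | os.PathLike, signals: np.ndarray, delimiter: str = "\t"
) -> None:
    """Write a t x m signal matrix as delimited text at full float precision."""
    np.savetxt(path, np.asarray(signals, dtype=float), delimiter=delimiter, fmt="%.17g")


def write_atlas(path: str | os.PathLike, geometry: AtlasGeometry) -> None:
    pd.DataFrame(
        {
            "roi_name": geometry.roi_names,
            "x": geometry.coords[:, 0],
            "y": geometry.coords[:, 1],
            "z": geometry.coords[:, 2],
        }
    ).to_csv(path, index=False)


def write_manifest(
    path: str | os.PathLike,
    records: Sequence[tuple[str, str, str]],
    extra_columns: dict[str, Sequence] | None = None,
) -> None:
    """Write a manifest CSV; ``extra_columns`` may carry provenance fields."""
    df = pd.DataFrame(records, columns=["subject_id", "path", "label"])
    for name, values in (extra_columns or {}).items():
        df[name] = list(values)
    df.to_csv(path, index=False)
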