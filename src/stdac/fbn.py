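"""Functional brain network estimation by Pearson correlation.

An FBN is the m x m matrix of sample Pearson correlations between ROI time
series. The classifier feature vector is the upper triangle excluding the
diagonal, in row-major order ((0,1), (0,2), ..., (0,m-1), (1,2), ...), length
m(m-1)/2 — the full connectome with no feature selection, no Fisher
transform, no thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_data import CohortError

__all__ = [
    "FBNMatrix",
    "pearson_fbn",
    "vectorize",
    "devectorize",
    "n_edges",
    "write_fbn_matrix",
    "write_edge_list",
]


@dataclass(frozen=True)
class FBNMatrix:
    """A Pearson-correlation network: symmetric, unit diagonal, entries in [-1,1]."""

    corr: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.corr, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError(f"corr must be square, got {c.shape}")
        object.__setattr__(self, "corr", c)

    @property
    def n_rois(self) -> int:
        return self.corr.shape[0]

    @property
    def features(self) -> np.ndarray:
        return vectorize(self.corr)


def n_edges(m: int) -> int:
    """Number of distinct node pairs: m(m-1)/2 (6670 for the 116-ROI AAL)."""
    return m * (m - 1) // 2


def pearson_fbn(sample: np.ndarray) -> FBNMatrix:
    """Sample Pearson correlation matrix of a time-series matrix (rows = time).

    Requires at least 3 rows (2 rows make every |correlation| exactly 1) and
    no constant column. The diagonal is forced to exactly 1 and off-diagonal
    entries are clipped to [-1, 1] against floating-point overshoot.
    """
    x = np.asarray(sample, dtype=float)
    if x.ndim != 2:
        raise ValueError(f"sample must be 2-D, got ndim={x.ndim}")
    if x.shape[0] < 3:
        raise CohortError(
            f"need at least 3 time points for a Pearson FBN, got {x.shape[0]}"
        )
    const = np.flatnonzero(x.std(axis=0) == 0)
    if const.size:
        raise CohortError(
            f"constant time series at node(s) {const.tolist()}; "
            "Pearson correlation undefined"
        )
    corr = np.corrcoef(x, rowvar=False)
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, 1.0)
    return FBNMatrix(corr=corr)


def vectorize(corr: np.ndarray) -> np.ndarray:
    """Upper triangle (excluding diagonal) in row-major order."""
    corr = np.asarray(corr)
    iu = np.triu_indices(corr.shape[0], k=1)
    return corr[iu].copy()


def devectorize(features: np.ndarray, m: int) -> np.ndarray:
    """Rebuild the symmetric unit-diagonal matrix from its edge vector."""
    features = np.asarray(features, dtype=float)
    if features.size != n_edges(m):
        raise ValueError(
            f"feature vector of length {features.size} does not match "
            f"m={m} ({n_edges(m)} edges)"
        )
    corr = np.eye(m)
    iu = np.triu_indices(m, k=1)
    corr[iu] = features
    corr[(iu[1], iu[0])] = features
    return corr


def write_fbn_matrix(path, fbn: FBNMatrix, delimiter: str = "\t") -> None:
    """Export the square correlation matrix as delimited text.

    With a ``.edge`` suffix this doubles as a BrainNet-Viewer edge file,
    which is simply a whitespace-delimited square adjacency matrix.
    """
    np.savetxt(path, fbn.corr, delimiter=delimiter, fmt="%.10g")


def write_edge_list(path, fbn: FBNMatrix, roi_names: list[str]) -> None:
    """Export edges as a TSV: roi_a, roi_b, weight (upper triangle order)."""
    if len(roi_names) != fbn.n_rois:
        raise ValueError("roi_names length does not match the FBN")
    iu = np.triu_indices(fbn.n_rois, k=1)
    with open(path, "w") as fh:
        fh.write("roi_a\troi_b\tweight\n")
        for a, b in zip(*iu):
            fh.write(f"{roi_names[a]}\t{roi_names[b]}\t{fbn.corr[a, b]:.10g}\n")
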