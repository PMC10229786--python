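"""Temporal augmentation: random discontinuous resampling of time points.

Instead of contiguous sliding windows, an augmented sample keeps l of the t
time points chosen uniformly at random without replacement (l < t), the same
index set applied jointly to every ROI so that inter-regional alignment — the
thing Pearson correlation measures — is preserved. This is a random-subset
analogue of jackknife resampling: averaging Pearson matrices over many such
subsamples approaches the full-sample estimate while each draw is a distinct
training sample.

A floor l_min keeps draws from becoming too sparse. Defaults are
l = ceil(0.7 t) and l_min = ceil(0.5 t); the degree (samples per subject)
defaults to 100. All randomness flows from one master seed: the draw for
replicate r of subject s is generated from SeedSequence([seed, s, r]), so a
sample set is byte-reproducible regardless of generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_data import AugmentedSample, SubjectTimeSeries

__all__ = [
    "TemporalConfig",
    "sample_time_indices",
    "temporal_augment_sample",
    "generate_temporal_set",
]


@dataclass(frozen=True)
class TemporalConfig:
    """Resampling parameters.

    l_frac / l_min_frac: fractions of t giving l = ceil(l_frac * t) and its
    floor l_min = ceil(l_min_frac * t). degree: samples per subject.
    randomize_l: draw l uniformly in [l_min, l] per replicate instead of
    holding it fixed. seed: master seed for every draw.
    """

    l_frac: float = 0.7
    l_min_frac: float = 0.5
    degree: int = 100
    randomize_l: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.l_min_frac <= self.l_frac <= 1:
            raise ValueError(
                f"need 0 < l_min_frac <= l_frac <= 1, got "
                f"({self.l_min_frac}, {self.l_frac})"
            )
        if self.degree < 1:
            raise ValueError(f"degree must be >= 1, got {self.degree}")

    def resolve_l(self, t: int) -> tuple[int, int]:
        """(l, l_min) for a series of t time points; both capped below t."""
        l = min(math.ceil(self.l_frac * t), t - 1) if self.l_frac < 1 else t - 1
        l_min = min(math.ceil(self.l_min_frac * t), l)
        if l < 2:
            raise ValueError(f"t={t} too short for temporal resampling")
        return l, l_min


def sample_time_indices(
    t: int,
    l: int,
    rng: np.random.Generator | int,
    l_min: int = 1,
) -> np.ndarray:
    """Draw l distinct time indices uniformly from 0..t-1, ascending order."""
    if l > t:
        raise ValueError(f"cannot select l={l} of t={t} time points")
    if l < l_min:
        raise ValueError(f"l={l} below the minimum l_min={l_min}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return np.sort(rng.choice(t, size=l, replace=False))


def temporal_augment_sample(
    subject: SubjectTimeSeries,
    indices: np.ndarray,
    replicate: int | None = None,
) -> AugmentedSample:
    """Row-slice the subject at the given time indices (all ROIs jointly)."""
    indices = np.asarray(indices, dtype=int)
    if indices.size and (indices.min() < 0 or indices.max() >= subject.n_timepoints):
        raise ValueError(
            f"time index out of range 0..{subject.n_timepoints - 1} for "
            f"subject {subject.subject_id!r}"
        )
    tag = f"__temporal_{replicate}" if replicate is not None else "__temporal"
    return AugmentedSample(
        subject_id=f"{subject.subject_id}{tag}",
        signals=subject.signals[indices, :],
        label=subject.label,
        source_subject_id=subject.subject_id,
        provenance={"method": "temporal", "indices": indices.tolist()},
    )


def generate_temporal_set(
    subjects: list[SubjectTimeSeries], cfg: TemporalConfig
) -> list[AugmentedSample]:
    """`degree` independently drawn subsamples per subject.

    Each draw's stream comes from SeedSequence([seed, subject_index,
    replicate_index]); labels are inherited and provenance records the exact
    indices used.
    """
    out: list[AugmentedSample] = []
    for si, subject in enumerate(subjects):
        t = subject.n_timepoints
        l, l_min = cfg.resolve_l(t)
        for ri in range(cfg.degree):
            rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, si, ri]))
            l_draw = int(rng.integers(l_min, l + 1)) if cfg.randomize_l else l
            idx = sample_time_indices(t, l_draw, rng, l_min=l_min)
            out.append(temporal_augment_sample(subject, idx, replicate=ri))
    return out
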