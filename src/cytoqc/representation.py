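"""Histogram representation of a preparation pipeline.

A pipeline batch is represented by one normalized histogram per nucleus
feature.  Each feature column is min-max normalized with *reference* bounds
``(m_l^-, m_l^+)`` shared across the whole QC module, discretized on
``n_bin`` equal-width bins over [0, 1], and renormalized to sum to 1.
Values falling outside the reference range are not binned: they shrink the
in-range mass and are thereby accounted for implicitly by the final
normalization — an out-of-range-heavy batch keeps a valid distribution while
its in-range shape carries the drift signal.

Binning convention: bins are half-open ``[k/n_bin, (k+1)/n_bin)`` with the
last bin closed so the reference maximum itself is countable.  The mapping
commutes with feature reduction: ``f(C @ P) == f(C) @ P`` for any reduction
matrix ``P``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .alerts import QcWarning
from .data import FeatureMatrix

DEFAULT_N_BIN = 100


@dataclass(frozen=True)
class ReductionMatrix:
    """Feature assignment encoded as an ordered tuple of source indices.

    Encodes the 0/1 assignment matrix with one 1 per output column and at
    most one per input row (indices are unique).
    """

    indices: tuple[int, ...]
    n_feat_in: int

    def __post_init__(self) -> None:
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("reduction indices must be unique")
        if any(not 0 <= i < self.n_feat_in for i in self.indices):
            raise ValueError("reduction index out of range")

    @property
    def n_sel(self) -> int:
        return len(self.indices)

    @property
    def is_identity(self) -> bool:
        return self.indices == tuple(range(self.n_feat_in))

    def as_matrix(self) -> np.ndarray:
        """Dense n_feat_in x n_sel 0/1 assignment matrix."""
        P = np.zeros((self.n_feat_in, self.n_sel))
        P[list(self.indices), np.arange(self.n_sel)] = 1.0
        return P


def identity_reduction(n_feat: int) -> ReductionMatrix:
    return ReductionMatrix(indices=tuple(range(n_feat)), n_feat_in=n_feat)


@dataclass
class NormalizationBounds:
    """Per-feature reference minima/maxima ``(m_l^-, m_l^+)``."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if self.lower.shape != self.upper.shape:
            raise ValueError("lower/upper must share shape")
        if np.any(self.lower > self.upper):
            raise ValueError("lower bound exceeds upper bound")

    @property
    def n_feat(self) -> int:
        return self.lower.shape[0]

    @property
    def degenerate(self) -> np.ndarray:
        """Boolean mask of features with a collapsed (zero-width) range."""
        return self.lower == self.upper


@dataclass
class DistributionMatrix:
    """Column-stochastic per-feature histograms of one pipeline batch."""

    columns: np.ndarray  # (n_bin, n_f)
    feature_ids: list[str]
    in_range_counts: np.ndarray  # per-feature count of values binned

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=float)
        if self.columns.ndim != 2:
            raise ValueError("columns must be 2-D (n_bin, n_f)")
        if self.columns.shape[1] != len(self.feature_ids):
            raise ValueError("feature_ids length must match column count")

    @property
    def n_bin(self) -> int:
        return self.columns.shape[0]

    @property
    def n_feat(self) -> int:
        return self.columns.shape[1]


def compute_bounds(matrices: list[FeatureMatrix]) -> NormalizationBounds:
    """Per-feature min/max over the rows of all supplied matrices."""
    if not matrices:
        raise ValueError("at least one feature matrix is required")
    ids = matrices[0].feature_ids
    for m in matrices[1:]:
        if m.feature_ids != ids:
            raise ValueError("inconsistent feature_ids across matrices")
    lower = np.min([m.values.min(axis=0) for m in matrices], axis=0)
    upper = np.max([m.values.max(axis=0) for m in matrices], axis=0)
    bounds = NormalizationBounds(lower=lower, upper=upper)
    if bounds.degenerate.any():
        bad = [ids[i] for i in np.flatnonzero(bounds.degenerate)]
        warnings.warn(f"degenerate (constant) features: {bad}", QcWarning, stacklevel=2)
    return bounds


def to_distribution(
    C: FeatureMatrix,
    bounds: NormalizationBounds,
    n_bin: int = DEFAULT_N_BIN,
) -> DistributionMatrix:
    """Map a feature matrix to its normalized per-feature histograms.

    Degenerate features and features whose values all fall out of range get a
    uniform column plus a QC warning: the distance stays well-defined while
    the anomaly is surfaced.
    """
    if n_bin < 2:
        raise ValueError("n_bin must be >= 2")
    if bounds.n_feat != C.n_feat:
        raise ValueError("bounds do not match the feature matrix")
    n_f = C.n_feat
    cols = np.empty((n_bin, n_f))
    counts = np.zeros(n_f, dtype=int)
    degenerate = bounds.degenerate
    for l in range(n_f):
        if degenerate[l]:
            _warn_uniform(C.feature_ids[l], "degenerate bounds")
            cols[:, l] = 1.0 / n_bin
            continue
        scaled = (C.values[:, l] - bounds.lower[l]) / (
            bounds.upper[l] - bounds.lower[l]
        )
        in_range = (scaled >= 0.0) & (scaled <= 1.0)
        kept = scaled[in_range]
        if kept.size == 0:
            _warn_uniform(C.feature_ids[l], "all values out of the reference range")
            cols[:, l] = 1.0 / n_bin
            continue
        idx = np.minimum((kept * n_bin).astype(int), n_bin - 1)  # 1.0 -> last bin
        hist = np.bincount(idx, minlength=n_bin).astype(float)
        cols[:, l] = hist / kept.size
        counts[l] = kept.size
    return DistributionMatrix(
        columns=cols, feature_ids=list(C.feature_ids), in_range_counts=counts
    )


def _warn_uniform(feature_id: str, why: str) -> None:
    warnings.warn(
        f"feature {feature_id}: {why}; histogram set to uniform",
        QcWarning,
        stacklevel=3,
    )


def apply_reduction(obj, P: ReductionMatrix):
    """Select/permute feature columns of a FeatureMatrix or DistributionMatrix."""
    idx = list(P.indices)
    if isinstance(obj, FeatureMatrix):
        if obj.n_feat != P.n_feat_in:
            raise ValueError("reduction input dimension mismatch")
        return FeatureMatrix(
            values=obj.values[:, idx],
            feature_ids=[obj.feature_ids[i] for i in idx],
        )
    if isinstance(obj, DistributionMatrix):
        if obj.n_feat != P.n_feat_in:
            raise ValueError("reduction input dimension mismatch")
        return DistributionMatrix(
            columns=obj.columns[:, idx],
            feature_ids=[obj.feature_ids[i] for i in idx],
            in_range_counts=obj.in_range_counts[idx],
        )
    raise TypeError(f"cannot reduce object of type {type(obj).__name__}")
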