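"""Per-reference feature selection (one-versus-all).

Each reference pipeline gets its own reduction matrix, chosen so the
retained features best separate that reference's nuclei from all other
references' nuclei.  The nuclei feature matrices of all references are
stacked, min-max normalized per column, and paired with a binary
one-vs-all label per reference; a univariate chi-squared filter or a greedy
mRMR (minimum-redundancy maximum-relevance) ranking then picks ``n_sel``
features.

The mRMR variant is the FCQ-style greedy quotient: relevance is the ANOVA
F-statistic against the label, redundancy the mean absolute Pearson
correlation with already-selected features, importance their quotient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.feature_selection import chi2, f_classif

from .alerts import QcWarning
from .data import FeatureMatrix
from .representation import ReductionMatrix

_REDUNDANCY_FLOOR = 1e-12


@dataclass
class StackedTrainingSet:
    """Min-max-normalized stack of all references' nuclei."""

    X_norm: np.ndarray              # (sum n_i, n_feat), entries in [0, 1]
    group_slices: list[slice]       # rows contributed by each reference
    feature_ids: list[str]

    @property
    def n_ref(self) -> int:
        return len(self.group_slices)

    @property
    def n_feat(self) -> int:
        return self.X_norm.shape[1]

    def labels(self, reference_index: int) -> np.ndarray:
        """One-vs-all 0/1 labels: 1 iff the row comes from this reference."""
        y = np.zeros(self.X_norm.shape[0], dtype=int)
        y[self.group_slices[reference_index]] = 1
        return y


def stack_and_normalize(feature_matrices: list[FeatureMatrix]) -> StackedTrainingSet:
    """Stack reference matrices in order and min-max normalize each column.

    Constant columns carry no one-vs-all signal; they are normalized to all
    zeros and flagged.
    """
    if not feature_matrices:
        raise ValueError("at least one feature matrix required")
    ids = feature_matrices[0].feature_ids
    for m in feature_matrices[1:]:
        if m.feature_ids != ids:
            raise ValueError("inconsistent feature_ids across references")
    X = np.vstack([m.values for m in feature_matrices])
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    span = hi - lo
    constant = span == 0
    if constant.any():
        bad = [ids[i] for i in np.flatnonzero(constant)]
        warnings.warn(
            f"constant features normalized to zero: {bad}", QcWarning, stacklevel=2
        )
    span = np.where(constant, 1.0, span)
    X_norm = (X - lo) / span
    slices = []
    start = 0
    for m in feature_matrices:
        slices.append(slice(start, start + m.n_rows))
        start += m.n_rows
    return StackedTrainingSet(X_norm=X_norm, group_slices=slices, feature_ids=ids)


def select_chi2(
    ts: StackedTrainingSet, reference_index: int, n_sel: int
) -> ReductionMatrix:
    """Chi-squared univariate filter: keep the n_sel lowest p-values.

    Ties (and undefined p-values from empty features, ranked last) are broken
    by ascending feature index for reproducibility.
    """
    _check_n_sel(ts, n_sel)
    y = ts.labels(reference_index)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn warns on zero-sum features
        _, pvals = chi2(ts.X_norm, y)
    pvals = np.where(np.isnan(pvals), np.inf, pvals)
    order = np.lexsort((np.arange(ts.n_feat), pvals))
    return ReductionMatrix(
        indices=tuple(sorted(int(i) for i in order[:n_sel])), n_feat_in=ts.n_feat
    )


def select_mrmr(
    ts: StackedTrainingSet, reference_index: int, n_sel: int
) -> ReductionMatrix:
    """Greedy mRMR: importance = F-statistic / mean |Pearson| with selected."""
    _check_n_sel(ts, n_sel)
    y = ts.labels(reference_index)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        F, _ = f_classif(ts.X_norm, y)
        corr = np.corrcoef(ts.X_norm, rowvar=False)
    F = np.where(np.isnan(F), 0.0, F)
    corr = np.atleast_2d(corr)
    corr = np.where(np.isnan(corr), 0.0, np.abs(corr))

    selected: list[int] = []
    remaining = np.ones(ts.n_feat, dtype=bool)
    while len(selected) < n_sel:
        if not selected:
            importance = F.copy()
        else:
            redundancy = corr[:, selected].mean(axis=1)
            importance = F / np.maximum(redundancy, _REDUNDANCY_FLOOR)
        importance = np.where(remaining, importance, -np.inf)
        pick = int(np.argmax(importance))  # argmax ties -> lowest index
        selected.append(pick)
        remaining[pick] = False
    return ReductionMatrix(indices=tuple(sorted(selected)), n_feat_in=ts.n_feat)


def _check_n_sel(ts: StackedTrainingSet, n_sel: int) -> None:
    if not 1 <= n_sel <= ts.n_feat:
        raise ValueError(f"n_sel must lie in [1, {ts.n_feat}], got {n_sel}")
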