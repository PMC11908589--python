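"""Histogram mapping: bounds, binning, out-of-range rule, reduction."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytoqc import (
    FeatureMatrix,
    NormalizationBounds,
    ReductionMatrix,
    apply_reduction,
    compute_bounds,
    identity_reduction,
    to_distribution,
)
from cytoqc.alerts import QcWarning


def _fm(values, ids=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    ids = ids or [f"f_{i:03d}" for i in range(values.shape[1])]
    return FeatureMatrix(values=values, feature_ids=ids)


class TestBounds:
    def test_single_matrix_min_max(self):
        M = _fm([[1.0, 5.0], [3.0, 2.0]])
        b = compute_bounds([M])
        np.testing.assert_array_equal(b.lower, [1.0, 2.0])
        np.testing.assert_array_equal(b.upper, [3.0, 5.0])

    def test_bounds_compose_elementwise(self):
        rng = np.random.default_rng(0)
        A, B = _fm(rng.random((20, 3))), _fm(rng.random((30, 3)))
        joint = compute_bounds([A, B])
        ba, bb = compute_bounds([A]), compute_bounds([B])
        np.testing.assert_array_equal(joint.lower, np.minimum(ba.lower, bb.lower))
        np.testing.assert_array_equal(joint.upper, np.maximum(ba.upper, bb.upper))

    def test_constant_feature_flagged_degenerate(self):
        M = _fm([[2.0, 1.0], [2.0, 3.0]])
        with pytest.warns(QcWarning):
            b = compute_bounds([M])
        np.testing.assert_array_equal(b.degenerate, [True, False])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_bounds([])


class TestHistogram:
    def test_two_bins_half_split(self):
        b = NormalizationBounds(lower=[0.0], upper=[1.0])
        F = to_distribution(_fm([[0.1], [0.6]]), b, n_bin=2)
        np.testing.assert_allclose(F.columns[:, 0], [0.5, 0.5])
        assert F.in_range_counts[0] == 2

    def test_out_of_range_values_dropped_then_renormalized(self):
        b = NormalizationBounds(lower=[0.0], upper=[1.0])
        F = to_distribution(_fm([[-0.5], [0.25], [0.75]]), b, n_bin=2)
        np.testing.assert_allclose(F.columns[:, 0], [0.5, 0.5])
        assert F.in_range_counts[0] == 2

    def test_upper_bound_lands_in_last_bin(self):
        b = NormalizationBounds(lower=[0.0], upper=[1.0])
        F = to_distribution(_fm([[1.0]]), b, n_bin=4)
        np.testing.assert_allclose(F.columns[:, 0], [0, 0, 0, 1])

    def test_matches_bruteforce_binning_oracle(self):
        """Vectorized binning equals direct per-value bin assignment."""
        rng = np.random.default_rng(7)
        vals = rng.normal(0.3, 0.5, size=(10_000, 2))
        M = _fm(vals)
        b = NormalizationBounds(lower=[-0.2, -0.1], upper=[0.9, 1.1])
        n_bin = 37
        F = to_distribution(M, b, n_bin=n_bin)
        for l in range(2):
            counts = np.zeros(n_bin)
            kept = 0
            for v in vals[:, l]:
                s = (v - b.lower[l]) / (b.upper[l] - b.lower[l])
                if not 0.0 <= s <= 1.0:
                    continue
                kept += 1
                for k in range(n_bin):
                    lo, hi = k / n_bin, (k + 1) / n_bin
                    if (lo <= s < hi) or (k == n_bin - 1 and s == 1.0):
                        counts[k] += 1
                        break
            np.testing.assert_allclose(F.columns[:, l], counts / kept, atol=0)

    def test_all_out_of_range_and_degenerate_give_uniform(self):
        b = NormalizationBounds(lower=[0.0, 2.0], upper=[1.0, 2.0])
        with pytest.warns(QcWarning):
            F = to_distribution(_fm([[5.0, 2.0], [7.0, 2.0]]), b, n_bin=4)
        np.testing.assert_allclose(F.columns, 0.25)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(8)
        vals = rng.random((500, 1))
        b = NormalizationBounds(lower=[0.0], upper=[1.0])
        F = to_distribution(_fm(vals), b)
        a, c = 3.5, -1.2
        b2 = NormalizationBounds(lower=[c], upper=[a + c])
        F2 = to_distribution(_fm(a * vals + c), b2)
        np.testing.assert_allclose(F.columns, F2.columns, atol=1e-12)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_columns_are_stochastic(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=(200, 3)) * rng.gamma(1.0, size=3)
        M = _fm(vals)
        bounds = compute_bounds([M])
        F = to_distribution(M, bounds, n_bin=50)
        np.testing.assert_allclose(F.columns.sum(axis=0), 1.0, atol=1e-9)
        assert np.all(F.columns >= 0.0) and np.all(F.columns <= 1.0)


class TestReduction:
    def test_identity_and_single_column(self):
        M = _fm(np.arange(12.0).reshape(4, 3))
        assert apply_reduction(M, identity_reduction(3)).values is not M.values
        np.testing.assert_array_equal(
            apply_reduction(M, identity_reduction(3)).values, M.values
        )
        P = ReductionMatrix(indices=(2,), n_feat_in=3)
        out = apply_reduction(M, P)
        np.testing.assert_array_equal(out.values[:, 0], M.values[:, 2])
        assert out.feature_ids == ["f_002"]

    def test_dimension_mismatch_rejected(self):
        M = _fm(np.ones((2, 3)))
        with pytest.raises(ValueError):
            apply_reduction(M, ReductionMatrix(indices=(0,), n_feat_in=4))

    def test_assignment_matrix_structure(self):
        P = ReductionMatrix(indices=(4, 1), n_feat_in=6)
        A = P.as_matrix()
        np.testing.assert_array_equal(A.sum(axis=0), [1.0, 1.0])
        assert np.all(A.sum(axis=1) <= 1.0)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_histogram_commutes_with_reduction(self, seed):
        """f(C P) == f(C) P — both routes computed independently."""
        rng = np.random.default_rng(seed)
        n_feat = int(rng.integers(2, 7))
        vals = rng.normal(size=(150, n_feat))
        M = _fm(vals)
        bounds = compute_bounds([M])
        k = int(rng.integers(1, n_feat + 1))
        idx = tuple(int(i) for i in rng.choice(n_feat, size=k, replace=False))
        P = ReductionMatrix(indices=idx, n_feat_in=n_feat)
        left = to_distribution(apply_reduction(M, P),
                               _reduce_bounds(bounds, idx), n_bin=30)
        right = apply_reduction(to_distribution(M, bounds, n_bin=30), P)
        np.testing.assert_allclose(left.columns, right.columns, atol=1e-12)
        assert left.feature_ids == right.feature_ids


def _reduce_bounds(bounds, idx):
    return NormalizationBounds(
        lower=bounds.lower[list(idx)], upper=bounds.upper[list(idx)]
    )
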