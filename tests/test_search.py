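"""Grid enumeration, accuracy/error metrics, filtering and refinement."""

from __future__ import annotations

import numpy as np
import pytest

from cytoqc import (
    CombinationRecord,
    ParamCombination,
    QcAlert,
    accuracy,
    enumerate_grid,
    error_from_distance_matrix,
    feature_configurations,
    grid_search,
    rank_and_refine,
    REFERENCE_GRID,
)
from cytoqc.alerts import QcWarning
from cytoqc.search import objective_h, parameter_frequencies
from cytoqc.search_params import N_PARAMETERS


def _theta(**over):
    base = dict(
        n_wsi=10, n_nuc=1000, intern_tau=None, use_distrib=False,
        omega="wasserstein", aggregator="max", sel_method=None, n_sel="all",
        seed=0,
    )
    base.update(over)
    return ParamCombination(**base)


class TestEnumeration:
    def test_reference_grid_size(self):
        """3 x 3 x 6 x 3 x 3 x 9 = 4374 combinations at a single seed."""
        combos = enumerate_grid(REFERENCE_GRID, single_seed=0)
        assert len(combos) == 4374
        assert len(set(combos)) == 4374

    def test_single_valued_grid(self):
        grid = {k: [v[0]] for k, v in REFERENCE_GRID.items()}
        assert len(enumerate_grid(grid, 0)) == 1

    def test_feature_configuration_count(self):
        """2 methods x 5 n_sel values = 10 configurations before the single
        no-selection configuration absorbs the two 'all' entries."""
        pairs = feature_configurations(REFERENCE_GRID["sel_method"],
                                       REFERENCE_GRID["n_sel"])
        assert len(pairs) == 10
        in_grid = {(c.sel_method, c.n_sel)
                   for c in enumerate_grid(REFERENCE_GRID, 0)}
        assert len(in_grid) == 9
        assert (None, "all") in in_grid

    def test_parameter_count(self):
        assert N_PARAMETERS == 8
        assert len(_theta().param_values()) == 8

    def test_selection_constraint_enforced(self):
        with pytest.raises(ValueError):
            _theta(sel_method=None, n_sel=20)
        with pytest.raises(ValueError):
            _theta(sel_method="chi2", n_sel="all")


class TestErrorMetric:
    def test_perfect_separation_gives_zero_error(self):
        D = np.array([[0.0, 0.4], [0.5, 0.1]])
        assert error_from_distance_matrix(D) == pytest.approx(0.0)

    def test_column_order_flip_gives_error_one(self):
        D = np.array([[0.2, 0.1], [0.3, 0.4]])
        assert error_from_distance_matrix(D) == pytest.approx(1.0)

    def test_dominant_diagonal_keeps_error_below_one(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 6))
            D = rng.uniform(0.3, 1.0, (n, n))
            D[np.diag_indices(n)] = rng.uniform(0.0, 0.2, n)
            assert error_from_distance_matrix(D) < 1.0

    def test_degenerate_column_warns(self):
        D = np.array([[0.2, 0.3], [0.2, 0.1]])
        with pytest.warns(QcWarning):
            e = error_from_distance_matrix(D)
        assert np.isfinite(e)

    def test_accuracy_counts_diagonal_constraints(self, module):
        assert accuracy(module) == 1.0


class TestRankAndRefine:
    def _records(self, n_valid, n_invalid=0, e_values=None):
        recs = []
        for k in range(n_valid):
            e = e_values[k] if e_values is not None else k / max(1, n_valid)
            recs.append(CombinationRecord(params=_theta(seed=k), A=1.0, E=e))
        for k in range(n_invalid):
            recs.append(
                CombinationRecord(params=_theta(seed=10_000 + k), A=0.5, E=1.0)
            )
        return recs

    def test_five_percent_rule_reproduces_printed_cut(self):
        """2860 valid combinations -> ceil(5%) = 143 kept in the error set."""
        recs = self._records(2860)
        res = rank_and_refine(recs, k1=150, k2=20,
                              refinement_seeds=[1], evaluate_accuracy=lambda t: 1.0)
        assert len(res.omega_set) == 143
        assert len(res.omega_minus) == 20

    def test_monotone_filtering(self):
        recs = self._records(40, n_invalid=10)
        res = rank_and_refine(recs, k1=10, k2=5, refinement_seeds=[1, 2],
                              evaluate_accuracy=lambda t: 1.0)
        assert set(res.omega_star) <= set(res.omega_minus)
        assert set(res.omega_minus) <= set(res.omega_set)
        assert set(res.omega_set) <= set(res.theta_star)
        assert len(res.theta_star) == 40

    def test_frequency_objective(self):
        """Combinations differing in one parameter split that frequency."""
        a = _theta(omega="wasserstein", aggregator="max")
        b = _theta(omega="jensen_shannon", aggregator="max")
        freqs = parameter_frequencies([a, b])
        assert freqs["aggregator"]["max"] == pytest.approx(1.0)
        assert freqs["omega"]["wasserstein"] == pytest.approx(0.5)
        assert objective_h(a, freqs) == pytest.approx(objective_h(b, freqs))
        # H sums 8 frequencies, each <= 1
        assert 0.0 < objective_h(a, freqs) <= N_PARAMETERS

    def test_objective_consistency_on_records(self):
        recs = self._records(20)
        res = rank_and_refine(recs, k1=20, k2=20, refinement_seeds=[1],
                              evaluate_accuracy=lambda t: 1.0)
        for r in recs:
            if r.T is not None:
                assert r.T == pytest.approx(1.0 - r.E + r.H)

    def test_all_invalid_raises_alert(self):
        recs = self._records(0, n_invalid=5)
        with pytest.raises(QcAlert):
            rank_and_refine(recs, k1=5, k2=2, refinement_seeds=[1],
                            evaluate_accuracy=lambda t: 1.0)

    def test_unstable_survivors_raise_alert(self):
        recs = self._records(10)
        with pytest.raises(QcAlert):
            rank_and_refine(recs, k1=5, k2=2, refinement_seeds=[1, 2],
                            evaluate_accuracy=lambda t: 0.5)

    def test_bad_k_rejected(self):
        with pytest.raises(ValueError):
            rank_and_refine(self._records(5), k1=0, k2=1,
                            refinement_seeds=[1], evaluate_accuracy=lambda t: 1.0)


class TestGridSearchEndToEnd:
    def test_scaled_down_search_returns_stable_combinations(self, cohort):
        """On a well-separated cohort the reduced search keeps valid,
        seed-stable combinations that re-validate on fresh seeds."""
        _, refs, vals = cohort
        grid = {
            "n_wsi": [5],
            "n_nuc": [1000],
            "intern_tau": [None],
            "use_distrib": [False, True],
            "omega": ["wasserstein", "bhattacharyya"],
            "aggregator": ["max", "mean"],
            "sel_method": ["chi2"],
            "n_sel": [3, "all"],
        }
        res = grid_search(
            refs, vals, grid, single_seed=0,
            refinement_seeds=list(range(1, 6)),
            k1=8, k2=4, error_fraction=0.5,
        )
        assert res.omega_star
        assert set(res.omega_star) <= set(res.omega_minus)
        retained = res.retained
        from cytoqc import calibrate

        for s in (101, 202):
            m = calibrate(refs, vals, retained.with_seed(s))
            assert m.diagnostics.accuracy == 1.0
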