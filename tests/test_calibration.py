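"""Calibration: weights, constraints-by-construction, alerts, merging."""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pytest

from cytoqc import (
    ParamCombination,
    QcAlert,
    calibrate,
    generate_batch,
    make_pipeline_profile,
    merge_references,
)
from cytoqc.alerts import ALERT_SMALL_ALPHA


def _ample_params(n_wsi, nuclei_per_wsi, seed=3, **over):
    """Parameters whose extraction keeps every nucleus (deterministic)."""
    base = dict(
        n_wsi=n_wsi, n_nuc=n_wsi * nuclei_per_wsi, intern_tau=None,
        use_distrib=False, omega="wasserstein", aggregator="max",
        sel_method=None, n_sel="all", seed=seed,
    )
    base.update(over)
    return ParamCombination(**base)


class TestCalibrate:
    def test_well_separated_cohort_is_valid(self, cohort, module):
        """All diagonal similarity constraints hold: accuracy 1, no alerts."""
        assert module.n_ref == 3
        diag = module.diagnostics
        assert diag.accuracy == 1.0
        assert diag.diagonal_ok.all()
        assert diag.alerts == []
        assert np.all(module.alphas > 0)

    def test_dissimilarity_constraints_hold_by_construction(self, module):
        """Every foreign validation batch sits at or beyond the weight."""
        D = module.diagnostics.distance_matrix
        n = module.n_ref
        for j in range(n):
            for i in range(n):
                if i != j:
                    assert D[j, i] >= module.alphas[j]

    def test_weights_are_minimum_foreign_distance(self, module):
        D = module.diagnostics.distance_matrix
        for i in range(module.n_ref):
            foreign = [D[i, j] for j in range(module.n_ref) if j != i]
            assert module.alphas[i] == pytest.approx(min(foreign), abs=1e-12)

    def test_identical_reference_and_validation_batches(self):
        """Self-similarity: diagonal distances are exactly 0 < alpha."""
        profiles = [make_pipeline_profile(s, 4, 0.4, pipeline_id=f"p{s}")
                    for s in (1, 2)]
        batches = [generate_batch(p, 3, 150, seed=10 + k)
                   for k, p in enumerate(profiles)]
        params = _ample_params(3, 150)
        module = calibrate(batches, batches, params)
        np.testing.assert_allclose(
            np.diag(module.diagnostics.distance_matrix), 0.0, atol=1e-12
        )
        assert module.diagnostics.accuracy == 1.0

    def test_near_clone_pipelines_get_small_alpha_alert(self):
        """Two pipelines drawn from one profile yield small, flagged weights."""
        clone = make_pipeline_profile(7, 5, 0.4)
        others = [make_pipeline_profile(s, 5, 0.4) for s in (8, 9)]
        profiles = [replace(clone, pipeline_id="c1"),
                    replace(clone, pipeline_id="c2"),
                    replace(others[0], pipeline_id="p3"),
                    replace(others[1], pipeline_id="p4")]
        refs = [generate_batch(p, 4, 300, seed=20 + k)
                for k, p in enumerate(profiles)]
        vals = [generate_batch(p, 4, 300, seed=40 + k)
                for k, p in enumerate(profiles)]
        module = calibrate(refs, vals, _ample_params(4, 300))
        a = {r.reference_id: r.alpha for r in module.references}
        assert max(a["c1"], a["c2"]) < min(a["p3"], a["p4"])
        codes = {c for c, _ in module.diagnostics.alerts}
        assert ALERT_SMALL_ALPHA in codes

    def test_indistinguishable_pipelines_raise_zero_alpha_alert(self):
        prof = make_pipeline_profile(5, 4, 0.2)
        b = generate_batch(prof, 3, 100, seed=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with pytest.raises(QcAlert):
                calibrate([b, b], [b, b], _ample_params(3, 100))

    def test_recalibration_is_bit_reproducible(self, cohort, base_params):
        _, refs, vals = cohort
        m1 = calibrate(refs, vals, base_params)
        m2 = calibrate(refs, vals, base_params)
        np.testing.assert_array_equal(m1.alphas, m2.alphas)
        for r1, r2 in zip(m1.references, m2.references):
            np.testing.assert_array_equal(r1.R.columns, r2.R.columns)

    def test_mismatched_batch_counts_rejected(self, cohort, base_params):
        _, refs, vals = cohort
        with pytest.raises(ValueError):
            calibrate(refs, vals[:2], base_params)


@pytest.fixture(scope="module")
def clone_module():
    clone = make_pipeline_profile(7, 5, 0.4)
    profiles = [replace(clone, pipeline_id="c1"),
                replace(clone, pipeline_id="c2"),
                replace(make_pipeline_profile(8, 5, 0.4), pipeline_id="p3")]
    refs = [generate_batch(p, 4, 300, seed=60 + k)
            for k, p in enumerate(profiles)]
    vals = [generate_batch(p, 4, 300, seed=80 + k)
            for k, p in enumerate(profiles)]
    return calibrate(refs, vals, _ample_params(4, 300))


class TestMerge:

    def test_merging_clones_raises_their_weights(self, clone_module):
        merged = merge_references(clone_module, {"c1", "c2"})
        before = {r.reference_id: r.alpha for r in clone_module.references}
        after = {r.reference_id: r.alpha for r in merged.references}
        assert after["c1"] > before["c1"]
        assert after["c2"] > before["c2"]
        # each merged weight is now the distance to the only foreign pipeline
        D = clone_module.diagnostics.distance_matrix
        ids = clone_module.reference_ids()
        assert after["c1"] == pytest.approx(D[ids.index("c1"), ids.index("p3")])
        assert after["p3"] == pytest.approx(before["p3"])

    def test_merge_all_rejected(self, clone_module):
        with pytest.raises(ValueError):
            merge_references(clone_module, {"c1", "c2", "p3"})

    def test_unknown_id_rejected(self, clone_module):
        with pytest.raises(KeyError):
            merge_references(clone_module, {"c1", "nope"})

    def test_disjoint_merge_leaves_other_weights_unchanged(self, cohort, module):
        merged = merge_references(module, set(module.reference_ids()[:2]))
        assert merged.references[2].alpha == pytest.approx(
            module.references[2].alpha
        )
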