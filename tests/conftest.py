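"""Shared fixtures: small synthetic cohorts and calibrated modules.

All fixtures are generated programmatically and sized so the whole suite
runs in minutes on one CPU; separation 0.35 on the abstract feature scale is
large relative to the component noise (sigma 0.08), giving well-separated
pipelines.
"""

from __future__ import annotations

import numpy as np
import pytest

from cytoqc import (
    ParamCombination,
    calibrate,
    make_cohort,
)

COHORT_KW = dict(
    n_pipelines=3,
    n_feat=6,
    separation=0.35,
    n_wsi=5,
    nuclei_per_wsi=400,
    seed=42,
)


@pytest.fixture(scope="session")
def cohort():
    """(profiles, reference batches, validation batches) — well separated."""
    return make_cohort(**COHORT_KW)


@pytest.fixture(scope="session")
def base_params():
    return ParamCombination(
        n_wsi=COHORT_KW["n_wsi"],
        n_nuc=1000,
        intern_tau=None,
        use_distrib=True,
        omega="wasserstein",
        aggregator="max",
        sel_method=None,
        n_sel="all",
        seed=7,
    )


@pytest.fixture(scope="session")
def module(cohort, base_params):
    _, refs, vals = cohort
    return calibrate(refs, vals, base_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_histogram(rng: np.random.Generator, n_bin: int) -> np.ndarray:
    """A random column-stochastic histogram (sparse support half the time)."""
    h = rng.gamma(0.5, size=n_bin)
    if rng.random() < 0.5:
        mask = rng.random(n_bin) < 0.3
        h = h * mask
        if h.sum() == 0:
            h[int(rng.integers(n_bin))] = 1.0
    return h / h.sum()
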