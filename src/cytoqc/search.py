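"""Grid-search validation of QC-module parameters.

The search enumerates the parameter grid at a single seed, calibrates a
module per combination, and filters in three steps: keep the valid
combinations (accuracy 1), keep the lowest-error fraction of them, then
keep the combinations ranked best by the frequency-augmented objective
``T = 1 - E + H``, where ``H`` sums, over the eight parameters, how
frequently the combination's value occurs among the low-error set — a
stability prior favouring values that many good combinations share.
Survivors are finally re-validated under fresh seeds; only seed-stable
combinations are retained.  An empty valid or stable set is a QC alert.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .alerts import (
    ALERT_EMPTY_STABLE_SET,
    ALERT_EMPTY_VALID_SET,
    QcAlert,
    QcWarning,
)
from .calibration import DEFAULT_BETA, QcModule, calibrate
from .data import WsiBatch
from .distances import distribution_distance
from .representation import DEFAULT_N_BIN, apply_reduction
from .search_params import ParamCombination

DEFAULT_K1 = 150
DEFAULT_K2 = 20
DEFAULT_ERROR_FRACTION = 0.05

#: Grid used in the reference experiments (one seed; debris handled apart).
REFERENCE_GRID = {
    "n_wsi": [10, 20, 30],
    "n_nuc": [1_000, 10_000, 100_000],
    "intern_tau": [None, 0.2, 0.4],
    "use_distrib": [False, True],
    "omega": ["wasserstein", "bhattacharyya", "jensen_shannon"],
    "aggregator": ["max", "mean", "median"],
    "sel_method": ["chi2", "mrmr"],
    "n_sel": [10, 20, 50, 100, "all"],
}


def feature_configurations(
    sel_methods: list[str], n_sel_values: list
) -> list[tuple[str, object]]:
    """All (method, n_sel) pairs tested for the feature-selection stage.

    This is the raw product; inside the grid the pairs pointing at
    ``n_sel="all"`` collapse to the single no-selection configuration.
    """
    return [(m, s) for m in sel_methods for s in n_sel_values]


def enumerate_grid(grid: dict, single_seed: int) -> list[ParamCombination]:
    """Cartesian product of the grid under the feature-selection constraint.

    The nuclei-selection composition is the product of the ellipse options
    (including "absent") with the even-sampling switch — the empty
    composition is legal.  Feature configurations pair each selection method
    with each finite ``n_sel``, plus the single no-selection configuration
    when ``"all"`` is offered.
    """
    for key in REFERENCE_GRID:
        if key not in grid or not grid[key]:
            raise ValueError(f"grid is missing values for {key!r}")
    feat_configs: list[tuple[str | None, int | str]] = [
        (m, s) for m in grid["sel_method"] for s in grid["n_sel"] if s != "all"
    ]
    if "all" in grid["n_sel"]:
        feat_configs.append((None, "all"))
    combos = []
    for n_wsi, n_nuc, tau, distrib, omega, agg, (meth, n_sel) in product(
        grid["n_wsi"],
        grid["n_nuc"],
        grid["intern_tau"],
        grid["use_distrib"],
        grid["omega"],
        grid["aggregator"],
        feat_configs,
    ):
        combos.append(
            ParamCombination(
                n_wsi=n_wsi,
                n_nuc=n_nuc,
                intern_tau=tau,
                use_distrib=distrib,
                omega=omega,
                aggregator=agg,
                sel_method=meth,
                n_sel=n_sel,
                seed=single_seed,
            )
        )
    return combos


def accuracy(module: QcModule, val_batches: list[WsiBatch] | None = None) -> float:
    """Fraction of references whose own validation batch is inside its weight.

    With weights defined as the minimum foreign distance, the dissimilarity
    constraints hold by construction, so validity reduces to the normalized
    count of diagonal (similarity) constraints met.
    """
    D, alphas = _distance_matrix(module, val_batches)
    return float(np.mean(np.diag(D) < alphas))


def error(module: QcModule, val_batches: list[WsiBatch] | None = None) -> float:
    """Margin-based error over the column-normalized cross-distance matrix."""
    D, _ = _distance_matrix(module, val_batches)
    return error_from_distance_matrix(D)


def error_from_distance_matrix(D: np.ndarray) -> float:
    """``E = 1 - min_i min_{j != i} (D~_{i,j} - D~_{i,i})``.

    Columns are min-max normalized for stability; a degenerate column (all
    references equidistant from that validation pipeline) is set to zeros
    with a warning.
    """
    D = np.asarray(D, dtype=float)
    n_ref = D.shape[0]
    if D.shape != (n_ref, n_ref) or n_ref < 2:
        raise ValueError("D must be square with at least two references")
    mu_lo = D.min(axis=0)
    mu_hi = D.max(axis=0)
    span = mu_hi - mu_lo
    degenerate = span == 0
    if degenerate.any():
        warnings.warn(
            f"degenerate distance-matrix columns: {np.flatnonzero(degenerate).tolist()}",
            QcWarning,
            stacklevel=2,
        )
    span = np.where(degenerate, 1.0, span)
    Dn = (D - mu_lo) / span
    Dn[:, degenerate] = 0.0
    margins = [
        Dn[i, j] - Dn[i, i] for i in range(n_ref) for j in range(n_ref) if j != i
    ]
    return float(1.0 - min(margins))


def _distance_matrix(module: QcModule, val_batches):
    if val_batches is None:
        if module.diagnostics is None:
            raise ValueError("module carries no diagnostics; pass val_batches")
        return module.diagnostics.distance_matrix, module.alphas
    from .qc import represent_batch

    n_ref = module.n_ref
    D = np.empty((n_ref, n_ref))
    spec = module.distance_spec
    for j, batch in enumerate(val_batches):
        F = represent_batch(batch, module)
        for i, ref in enumerate(module.references):
            D[i, j] = distribution_distance(
                ref.R, apply_reduction(F, ref.P), spec
            ).value
    return D, module.alphas


@dataclass
class CombinationRecord:
    params: ParamCombination
    A: float
    E: float
    H: float | None = None
    T: float | None = None

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "A": self.A,
            "E": self.E,
            "H": self.H,
            "T": self.T,
        }


@dataclass
class SearchResult:
    """Outcome of the three filtering steps plus seed refinement."""

    records: list[CombinationRecord]
    theta_star: list[ParamCombination]
    omega_set: list[ParamCombination]
    omega_minus: list[ParamCombination]
    omega_star: list[ParamCombination]
    alerts: list[tuple[str, str]] = field(default_factory=list)

    @property
    def retained(self) -> ParamCombination | None:
        return self.omega_star[0] if self.omega_star else None


def parameter_frequencies(
    omega_set: list[ParamCombination],
) -> dict[str, dict[object, float]]:
    """Per-parameter value frequencies ``h_p(t)`` over the low-error set."""
    n = len(omega_set)
    freqs: dict[str, dict[object, float]] = {}
    for theta in omega_set:
        for p, t in theta.param_values().items():
            freqs.setdefault(p, {})
            freqs[p][t] = freqs[p].get(t, 0.0) + 1.0 / n
    return freqs


def objective_h(theta: ParamCombination, freqs: dict[str, dict[object, float]]) -> float:
    """``H(theta)``: sum of the combination's parameter-value frequencies."""
    return float(
        sum(freqs[p].get(t, 0.0) for p, t in theta.param_values().items())
    )


def rank_and_refine(
    records: list[CombinationRecord],
    k1: int,
    k2: int,
    refinement_seeds: list[int],
    evaluate_accuracy,
    error_fraction: float = DEFAULT_ERROR_FRACTION,
) -> SearchResult:
    """Filter combination records and refine the survivors by seed stability.

    ``evaluate_accuracy(theta)`` must recalibrate under the (re-seeded)
    combination and return its accuracy; it is called for every survivor and
    every refinement seed.  Raises a QC alert when no combination is valid or
    none survives refinement.
    """
    if k1 < 1 or k2 < 1:
        raise ValueError("k1 and k2 must be >= 1")
    theta_star = [r for r in records if r.A == 1.0]
    if not theta_star:
        raise QcAlert(
            ALERT_EMPTY_VALID_SET,
            "no valid parameter combination: reconsider the reference and "
            "validation sets or the processing pipeline",
        )
    keep = min(k1, math.ceil(error_fraction * len(theta_star)))
    omega_recs = sorted(
        theta_star, key=lambda r: r.E
    )[:keep]  # stable sort: ties by enumeration order
    omega_set = [r.params for r in omega_recs]

    freqs = parameter_frequencies(omega_set)
    for r in omega_recs:
        r.H = objective_h(r.params, freqs)
        r.T = 1.0 - r.E + r.H
    order = sorted(range(len(omega_recs)), key=lambda k: -omega_recs[k].T)
    omega_minus_recs = [omega_recs[k] for k in order[: min(k2, len(omega_recs))]]
    omega_minus = [r.params for r in omega_minus_recs]

    omega_star = []
    for r in omega_minus_recs:
        stable = all(
            evaluate_accuracy(r.params.with_seed(s)) == 1.0
            for s in refinement_seeds
        )
        if stable:
            omega_star.append(r.params)
    alerts: list[tuple[str, str]] = []
    if not omega_star:
        raise QcAlert(
            ALERT_EMPTY_STABLE_SET,
            "no combination remained valid across the refinement seeds",
        )
    return SearchResult(
        records=records,
        theta_star=[r.params for r in theta_star],
        omega_set=omega_set,
        omega_minus=omega_minus,
        omega_star=omega_star,
        alerts=alerts,
    )


def grid_search(
    ref_batches: list[WsiBatch],
    val_batches: list[WsiBatch],
    grid: dict,
    single_seed: int,
    refinement_seeds: list[int],
    k1: int = DEFAULT_K1,
    k2: int = DEFAULT_K2,
    error_fraction: float = DEFAULT_ERROR_FRACTION,
    beta: float = DEFAULT_BETA,
    n_bin: int = DEFAULT_N_BIN,
) -> SearchResult:
    """Enumerate the grid, evaluate every combination, filter and refine.

    Evaluations are memoized per combination so the refinement step never
    recomputes a grid point it has already seen.
    """
    combos = enumerate_grid(grid, single_seed)
    cache: dict[ParamCombination, tuple[float, float]] = {}

    def evaluate(theta: ParamCombination) -> tuple[float, float]:
        if theta not in cache:
            cache[theta] = _eval(theta, ref_batches, val_batches, beta, n_bin)
        return cache[theta]

    records = [
        CombinationRecord(params=theta, A=evaluate(theta)[0], E=evaluate(theta)[1])
        for theta in combos
    ]

    def evaluate_accuracy(theta: ParamCombination) -> float:
        return evaluate(theta)[0]

    return rank_and_refine(
        records,
        k1=k1,
        k2=k2,
        refinement_seeds=refinement_seeds,
        evaluate_accuracy=evaluate_accuracy,
        error_fraction=error_fraction,
    )


def _eval(theta, ref_batches, val_batches, beta, n_bin):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", QcWarning)
        try:
            module = calibrate(ref_batches, val_batches, theta, beta=beta, n_bin=n_bin)
        except QcAlert:
            return 0.0, 1.0  # indistinguishable pipelines: invalid combination
    if np.any(module.alphas >= 1.0):
        return 0.0, 1.0  # saturated weight: quality measure undefined
    A = module.diagnostics.accuracy
    E = error_from_distance_matrix(module.diagnostics.distance_matrix)
    return A, E
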