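"""Calibration of the QC module from reference and validation batches.

Each reference pipeline ``i`` ends up represented by a tuple
``(R_i, P_i, alpha_i)``: its histogram representation under its own
reduction matrix, and a weight ``alpha_i`` — the distance below which a
batch is deemed *similar* to reference ``i``.  The weight is set to the
smallest distance from ``R_i`` to any *foreign* validation pipeline, so the
dissimilarity constraints against all foreign pipelines hold by
construction; whether each reference's own validation batch lands inside
its weight (the diagonal, or similarity, constraint) is the calibration's
empirical accuracy.

Normalization bounds are the per-feature min/max over all reference and
validation nuclei jointly; future batches may fall outside them, which the
histogram mapping absorbs through its out-of-range rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .alerts import (
    ALERT_DIAGONAL,
    ALERT_SATURATED_ALPHA,
    ALERT_SMALL_ALPHA,
    ALERT_ZERO_ALPHA,
    QcWarning,
)
from .data import WsiBatch
from .distances import DistanceSpec, distribution_distance
from .feature_selection import select_chi2, select_mrmr, stack_and_normalize
from .representation import (
    DEFAULT_N_BIN,
    DistributionMatrix,
    NormalizationBounds,
    ReductionMatrix,
    apply_reduction,
    compute_bounds,
    identity_reduction,
    to_distribution,
)
from .search_params import ParamCombination
from .selection import extract_feature_matrix

DEFAULT_BETA = 0.7
SMALL_ALPHA_FACTOR = 0.25  # alpha below this fraction of the median is flagged


@dataclass
class ReferenceModel:
    """One calibrated reference pipeline: ``(R_i, P_i, alpha_i)`` + bounds."""

    reference_id: str
    R: DistributionMatrix
    P: ReductionMatrix
    alpha: float
    bounds: NormalizationBounds

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive (zero means an alert)")


@dataclass
class CalibrationReport:
    """Diagnostics produced while assembling the module."""

    distance_matrix: np.ndarray        # D[i, j] = d(R_i, f(phi(V_j)) P_i)
    diagonal_ok: np.ndarray            # per-reference Eq-style similarity check
    accuracy: float
    alerts: list[tuple[str, str]] = field(default_factory=list)  # (code, detail)


@dataclass
class QcModule:
    """The calibrated QC module: shared bounds plus one model per reference."""

    references: list[ReferenceModel]
    params: ParamCombination
    beta: float = DEFAULT_BETA
    n_bin: int = DEFAULT_N_BIN
    diagnostics: CalibrationReport | None = None
    validation_full: list[DistributionMatrix] | None = None  # for re-weighting

    def __post_init__(self) -> None:
        if len(self.references) < 2:
            raise ValueError("a QC module needs at least two references")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")

    @property
    def n_ref(self) -> int:
        return len(self.references)

    @property
    def bounds(self) -> NormalizationBounds:
        return self.references[0].bounds

    @property
    def distance_spec(self) -> DistanceSpec:
        return DistanceSpec(omega=self.params.omega, aggregator=self.params.aggregator)

    @property
    def alphas(self) -> np.ndarray:
        return np.array([r.alpha for r in self.references])

    def reference_ids(self) -> list[str]:
        return [r.reference_id for r in self.references]


def compute_weights(
    ref_reprs: list[DistributionMatrix],
    val_full: list[DistributionMatrix],
    reductions: list[ReductionMatrix],
    spec: DistanceSpec,
) -> np.ndarray:
    """Reference weights: ``alpha_i = min_{j != i} d(R_i, f(phi(V_j)) P_i)``.

    ``ref_reprs`` are the reference representations already under their own
    reduction; ``val_full`` the *unreduced* validation representations, so
    each can be re-reduced with every reference's matrix.
    """
    n_ref = len(ref_reprs)
    if len(val_full) != n_ref:
        raise ValueError("need one validation batch per reference")
    alphas = np.empty(n_ref)
    for i in range(n_ref):
        cross = [
            distribution_distance(
                ref_reprs[i], apply_reduction(val_full[j], reductions[i]), spec
            ).value
            for j in range(n_ref)
            if j != i
        ]
        alphas[i] = min(cross)
    return alphas


def _selection_seed(base_seed: int, index: int) -> int:
    child = np.random.SeedSequence(base_seed).spawn(index + 1)[index]
    return int(child.generate_state(1)[0] % (2**31))


def calibrate(
    ref_batches: list[WsiBatch],
    val_batches: list[WsiBatch],
    params: ParamCombination,
    beta: float = DEFAULT_BETA,
    n_bin: int = DEFAULT_N_BIN,
    use_debris_filter: bool = False,
) -> QcModule:
    """Build a QC module from matched reference and validation batches.

    Pipeline: nuclei extraction per batch, joint normalization bounds,
    per-reference one-vs-all feature selection over the stacked reference
    nuclei, reference representations, weights, then the diagonal
    (similarity) constraint check.  Alerts — a zero or anomalously small
    weight, or a violated diagonal constraint — are recorded in the
    diagnostics; calibration itself always completes unless a weight is
    exactly zero.
    """
    n_ref = len(ref_batches)
    if len(val_batches) != n_ref:
        raise ValueError("need equally many reference and validation batches")
    if n_ref < 2:
        raise ValueError("at least two reference pipelines are required")

    sel_specs_ref = [
        params.selection_spec(
            seed=_selection_seed(params.seed, k), use_debris_filter=use_debris_filter
        )
        for k in range(n_ref)
    ]
    sel_specs_val = [
        params.selection_spec(
            seed=_selection_seed(params.seed, n_ref + k),
            use_debris_filter=use_debris_filter,
        )
        for k in range(n_ref)
    ]
    ref_mats = [
        extract_feature_matrix(b, s) for b, s in zip(ref_batches, sel_specs_ref)
    ]
    val_mats = [
        extract_feature_matrix(b, s) for b, s in zip(val_batches, sel_specs_val)
    ]

    bounds = compute_bounds(ref_mats + val_mats)
    ref_full = [to_distribution(m, bounds, n_bin) for m in ref_mats]
    val_full = [to_distribution(m, bounds, n_bin) for m in val_mats]

    n_feat = ref_mats[0].n_feat
    if params.sel_method is None:
        reductions = [identity_reduction(n_feat) for _ in range(n_ref)]
    else:
        ts = stack_and_normalize(ref_mats)
        picker = select_chi2 if params.sel_method == "chi2" else select_mrmr
        reductions = [picker(ts, i, int(params.n_sel)) for i in range(n_ref)]

    spec = DistanceSpec(omega=params.omega, aggregator=params.aggregator)
    ref_reprs = [apply_reduction(ref_full[i], reductions[i]) for i in range(n_ref)]
    alphas = compute_weights(ref_reprs, val_full, reductions, spec)

    # Full cross-distance matrix D[i, j]; diagonal carries the similarity check.
    D = np.empty((n_ref, n_ref))
    for i in range(n_ref):
        for j in range(n_ref):
            D[i, j] = distribution_distance(
                ref_reprs[i], apply_reduction(val_full[j], reductions[i]), spec
            ).value

    alerts: list[tuple[str, str]] = []
    ids = [b.pipeline_id for b in ref_batches]
    for i, a in enumerate(alphas):
        if a == 0.0:
            alerts.append(
                (ALERT_ZERO_ALPHA, f"reference {ids[i]}: indistinguishable "
                 "from another pipeline (alpha = 0)")
            )
    for i, a in enumerate(alphas):
        # a saturated distance means the dissimilarity term of the quality
        # measure (coefficient alpha/(1-alpha)) is undefined for this module
        if a >= 1.0:
            alerts.append(
                (ALERT_SATURATED_ALPHA,
                 f"reference {ids[i]}: weight saturates at {a:.4g}; the "
                 "quality measure is undefined under this configuration")
            )
    median_alpha = float(np.median(alphas))
    for i, a in enumerate(alphas):
        if 0.0 < a < SMALL_ALPHA_FACTOR * median_alpha:
            alerts.append(
                (ALERT_SMALL_ALPHA,
                 f"reference {ids[i]}: weight {a:.4g} is small relative to the "
                 f"cohort median {median_alpha:.4g}")
            )
    diagonal_ok = np.diag(D) < alphas
    for i in np.flatnonzero(~diagonal_ok):
        alerts.append(
            (ALERT_DIAGONAL,
             f"reference {ids[i]}: own validation batch violates the "
             f"similarity constraint (d={D[i, i]:.4g} >= alpha={alphas[i]:.4g})")
        )
    accuracy = float(np.mean(diagonal_ok))
    report = CalibrationReport(
        distance_matrix=D,
        diagonal_ok=diagonal_ok,
        accuracy=accuracy,
        alerts=alerts,
    )
    if np.any(alphas == 0.0):
        warnings.warn(
            "calibration produced a zero reference weight", QcWarning, stacklevel=2
        )
        alphas = np.where(alphas == 0.0, np.nan, alphas)

    references = []
    for i in range(n_ref):
        if np.isnan(alphas[i]):
            raise _zero_alpha_error(ids[i])
        references.append(
            ReferenceModel(
                reference_id=ids[i],
                R=ref_reprs[i],
                P=reductions[i],
                alpha=float(alphas[i]),
                bounds=bounds,
            )
        )
    return QcModule(
        references=references,
        params=params,
        beta=beta,
        n_bin=n_bin,
        diagnostics=report,
        validation_full=val_full,
    )


def _zero_alpha_error(ref_id: str):
    from .alerts import QcAlert

    return QcAlert(
        ALERT_ZERO_ALPHA,
        f"reference {ref_id} has weight 0: two pipelines are indistinguishable",
    )


def merge_references(module: QcModule, ids: set[str] | list[str]) -> QcModule:
    """Treat the named references as one entity when computing weights.

    Their mutual distances are excluded from the minimum in the weight
    definition, so each merged reference's weight becomes its distance to the
    nearest *non-merged* pipeline.  Representations and reductions are kept
    separate (histograms are not pooled); non-merged references' weights are
    untouched only insofar as their minima never involved the merged pair's
    mutual distances — they are recomputed identically.
    """
    ids = set(ids)
    known = set(module.reference_ids())
    unknown = ids - known
    if unknown:
        raise KeyError(f"unknown reference ids: {sorted(unknown)}")
    if len(ids) < 2:
        raise ValueError("merging needs at least two references")
    if ids == known:
        raise ValueError("cannot merge all references: no foreign pipeline remains")
    if module.validation_full is None:
        raise ValueError("module lacks stored validation representations")

    spec = module.distance_spec
    merged_idx = {
        k for k, r in enumerate(module.references) if r.reference_id in ids
    }
    new_refs = []
    for i, ref in enumerate(module.references):
        excluded = merged_idx | {i} if i in merged_idx else {i}
        cross = [
            distribution_distance(
                ref.R, apply_reduction(module.validation_full[j], ref.P), spec
            ).value
            for j in range(module.n_ref)
            if j not in excluded
        ]
        alpha = min(cross)
        if alpha == 0.0:
            raise _zero_alpha_error(ref.reference_id)
        new_refs.append(
            ReferenceModel(
                reference_id=ref.reference_id,
                R=ref.R,
                P=ref.P,
                alpha=float(alpha),
                bounds=ref.bounds,
            )
        )
    return QcModule(
        references=new_refs,
        params=module.params,
        beta=module.beta,
        n_bin=module.n_bin,
        diagnostics=module.diagnostics,
        validation_full=module.validation_full,
    )
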