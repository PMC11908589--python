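"""Scoring an input batch against a calibrated QC module.

An input batch ``S`` is represented under each reference's reduction and the
module bounds, and encoded by a signed, weighted distance vector

    d_j(S) = d(R_j, f(phi(S)) P_j) / alpha_j - 1,

negative exactly when S sits inside reference j's similarity radius.  From
it derive:

* compatibility ``C_i(S)``: the fraction of the n_ref constraints satisfied
  when testing reference i (d_i < 0, and d_j >= 0 for every other j);
* quality ``Q_i(S) = beta * Q_i^r + (1 - beta) * Q_i^rbar``, blending
  closeness to reference i with remoteness from the others, bounded on
  [0, 1] and zero when no constraint is satisfied;
* the maximum-quality compatible reference, or an explicit alert that no
  reference fits and a new one should be integrated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .alerts import ALERT_NO_COMPATIBLE_REFERENCE, QcWarning
from .calibration import QcModule
from .data import WsiBatch
from .distances import distribution_distance
from .representation import apply_reduction, to_distribution
from .selection import extract_feature_matrix


@dataclass
class QcReport:
    """Scoring outcome for one batch against one tested reference."""

    batch_id: str
    tested_reference: str | None
    reference_ids: list[str]
    distance_vector: np.ndarray
    raw_distances: np.ndarray
    argmax_features: list[str]
    compatibility: float | None = None
    quality: float | None = None
    quality_similar: float | None = None
    quality_dissimilar: float | None = None
    best_reference: str | None = None
    alerts: list[tuple[str, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "batch_id": self.batch_id,
            "tested_reference": self.tested_reference,
            "reference_ids": self.reference_ids,
            "distance_vector": [float(v) for v in self.distance_vector],
            "raw_distances": [float(v) for v in self.raw_distances],
            "argmax_features": self.argmax_features,
            "compatibility": self.compatibility,
            "quality": self.quality,
            "quality_similar": self.quality_similar,
            "quality_dissimilar": self.quality_dissimilar,
            "best_reference": self.best_reference,
            "alerts": [list(a) for a in self.alerts],
        }


def represent_batch(S: WsiBatch, module: QcModule, seed: int | None = None):
    """Unreduced distribution matrix of S under the module's bounds."""
    spec = module.params.selection_spec(
        seed=module.params.seed if seed is None else seed
    )
    C = extract_feature_matrix(S, spec)
    return to_distribution(C, module.bounds, module.n_bin)


def distance_vector(
    S: WsiBatch, module: QcModule, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Signed weighted distances of S to every reference.

    Returns ``(d, raw, argmax_features)`` where ``raw`` holds the unweighted
    distances and ``argmax_features`` the per-reference feature attaining the
    maximum per-feature distance (the drift attribution signal).
    """
    F_full = represent_batch(S, module, seed=seed)
    spec = module.distance_spec
    n_ref = module.n_ref
    d = np.empty(n_ref)
    raw = np.empty(n_ref)
    argmax: list[str] = []
    for j, ref in enumerate(module.references):
        res = distribution_distance(ref.R, apply_reduction(F_full, ref.P), spec)
        raw[j] = res.value
        if ref.alpha == 0:
            raise ValueError("module invalid: zero reference weight")
        d[j] = res.value / ref.alpha - 1.0
        argmax.append(res.argmax_feature)
    return d, raw, argmax


def compatibility(d: np.ndarray, i: int) -> float:
    """Fraction of the n_ref (dis)similarity constraints satisfied for i."""
    d = np.asarray(d, dtype=float)
    n_ref = d.shape[0]
    if not 0 <= i < n_ref:
        raise IndexError("tested reference index out of range")
    hits = int(d[i] < 0.0) + int(np.sum(d[np.arange(n_ref) != i] >= 0.0))
    return hits / n_ref


def quality(
    d: np.ndarray, i: int, alphas: np.ndarray, beta: float
) -> tuple[float, float, float]:
    """Quality triple ``(Q, Q^r, Q^rbar)`` for tested reference i.

    ``Q^r = max(0, -d_i)`` rewards closeness to i; ``Q^rbar`` averages the
    positive foreign distances, each rescaled by ``alpha_j / (1 - alpha_j)``
    so that the maximal attainable distance maps to 1.
    """
    d = np.asarray(d, dtype=float)
    alphas = np.asarray(alphas, dtype=float)
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")
    n_ref = d.shape[0]
    if not 0 <= i < n_ref:
        raise IndexError("tested reference index out of range")
    foreign = [j for j in range(n_ref) if j != i]
    if np.any(alphas[foreign] >= 1.0):
        raise ValueError("module invalid: a foreign reference weight is >= 1")
    q_r = max(0.0, -float(d[i]))
    q_rbar = float(
        np.mean(
            [alphas[j] / (1.0 - alphas[j]) * max(0.0, float(d[j])) for j in foreign]
        )
    )
    q = beta * q_r + (1.0 - beta) * q_rbar
    return q, q_r, q_rbar


def score_batch(
    S: WsiBatch,
    module: QcModule,
    tested_reference: str | None = None,
    seed: int | None = None,
    batch_id: str | None = None,
) -> QcReport:
    """Full QC of one batch: distances, compatibility/quality, assignment."""
    d, raw, argmax = distance_vector(S, module, seed=seed)
    ids = module.reference_ids()
    report = QcReport(
        batch_id=batch_id or S.pipeline_id,
        tested_reference=tested_reference,
        reference_ids=ids,
        distance_vector=d,
        raw_distances=raw,
        argmax_features=argmax,
    )
    compat = np.array([compatibility(d, k) for k in range(module.n_ref)])
    eligible = np.flatnonzero(compat == 1.0)
    if eligible.size:
        qs = np.array(
            [quality(d, k, module.alphas, module.beta)[0] for k in eligible]
        )
        report.best_reference = ids[int(eligible[int(np.argmax(qs))])]
    else:
        report.alerts.append(
            (ALERT_NO_COMPATIBLE_REFERENCE,
             "no reference is compatible; a new reference should be "
             "integrated in the QC module")
        )
    if tested_reference is not None:
        i = ids.index(tested_reference)
        report.compatibility = compatibility(d, i)
        q, q_r, q_rbar = quality(d, i, module.alphas, module.beta)
        report.quality = q
        report.quality_similar = q_r
        report.quality_dissimilar = q_rbar
    return report


@dataclass
class BestReference:
    assignment: str | None
    quality: float | None
    alert: bool


def best_reference(
    S: WsiBatch, module: QcModule, seed: int | None = None
) -> BestReference:
    """Maximum-quality compatible reference, or an explicit alert."""
    d, _, _ = distance_vector(S, module, seed=seed)
    compat = [compatibility(d, k) for k in range(module.n_ref)]
    eligible = [k for k, c in enumerate(compat) if c == 1.0]
    if not eligible:
        return BestReference(assignment=None, quality=None, alert=True)
    qs = [quality(d, k, module.alphas, module.beta)[0] for k in eligible]
    best = eligible[int(np.argmax(qs))]  # ties -> lowest reference index
    return BestReference(
        assignment=module.reference_ids()[best], quality=float(max(qs)), alert=False
    )


def cut_stream(tables: list, n_wsi: int) -> list[list]:
    """Cut a WSI stream into contiguous non-overlapping batches of n_wsi.

    The trailing remainder is dropped with a warning, mirroring routine
    monitoring where only full batches are scored.
    """
    if n_wsi < 1:
        raise ValueError("n_wsi must be >= 1")
    n_full = len(tables) // n_wsi
    rest = len(tables) - n_full * n_wsi
    if rest:
        warnings.warn(
            f"dropping {rest} trailing WSIs not filling a batch of {n_wsi}",
            QcWarning,
            stacklevel=2,
        )
    return [tables[k * n_wsi : (k + 1) * n_wsi] for k in range(n_full)]
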