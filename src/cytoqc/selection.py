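"""Nuclei selection: composable filters and per-WSI sampling.

Segmented nuclei are not all equally informative: slide edges carry dense
centrifugation clusters prone to segmentation errors, clusters bias spatial
sampling, and debris objects distort feature distributions.  Three base
methods address these and can be composed, together with the total number of
nuclei ``n_nuc`` to keep:

* ellipse filter — keep nuclei inside an ellipse centred on the slide whose
  full axes are a fraction ``tau`` of the slide width and height;
* spatially even sampling — stratify the slide into a grid and draw nuclei
  round-robin across occupied cells, avoiding cluster oversampling;
* debris filter — drop rows flagged as debris.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .alerts import QcWarning
from .data import FeatureMatrix, NucleusTable, WsiBatch, default_feature_ids


@dataclass(frozen=True)
class SelectionSpec:
    """Composition of nuclei-selection methods plus the sampling budget.

    ``intern_tau=None`` disables the ellipse filter; ``use_distrib=False``
    falls back to uniform random per-WSI sampling.  The empty composition
    (no filter, uniform sampling) is a legal configuration.
    """

    n_nuc: int
    seed: int
    intern_tau: float | None = None
    use_distrib: bool = False
    use_debris_filter: bool = False

    def __post_init__(self) -> None:
        if self.n_nuc < 1:
            raise ValueError("n_nuc must be >= 1")
        if self.intern_tau is not None and not 0.0 < self.intern_tau <= 1.0:
            raise ValueError("intern_tau must lie in (0, 1]")


def select_intern(
    table: NucleusTable,
    tau: float,
    width: float | None = None,
    height: float | None = None,
) -> NucleusTable:
    """Keep nuclei inside the centred ellipse with semi-axes tau*W/2, tau*H/2."""
    if not 0.0 < tau <= 1.0:
        raise ValueError("tau must lie in (0, 1]")
    w = table.width if width is None else width
    h = table.height if height is None else height
    ax, ay = tau * w / 2.0, tau * h / 2.0
    u = (table.x - w / 2.0) / ax
    v = (table.y - h / 2.0) / ay
    keep = u * u + v * v <= 1.0
    return table.take(np.flatnonzero(keep))


def select_debris(table: NucleusTable) -> NucleusTable:
    """Drop rows flagged as debris."""
    keep = np.flatnonzero(~table.is_debris)
    if keep.size == 0:
        warnings.warn(
            f"WSI {table.wsi_id}: every nucleus is flagged as debris",
            QcWarning,
            stacklevel=2,
        )
    return table.take(keep)


def select_distrib(
    table: NucleusTable,
    target_n: int,
    seed: int,
    width: float | None = None,
    height: float | None = None,
) -> NucleusTable:
    """Spatially even sampling of up to ``target_n`` nuclei.

    The slide is tiled into a g x g grid with ``g = ceil(sqrt(target_n))``;
    occupied cells are visited round-robin, taking one shuffled nucleus per
    visit without replacement, so dense clusters cannot dominate.
    """
    if target_n < 1:
        raise ValueError("target_n must be >= 1")
    if table.n == 0:
        warnings.warn("empty nucleus table: nothing to select", QcWarning, stacklevel=2)
        return table
    if target_n >= table.n:
        return table

    w = table.width if width is None else width
    h = table.height if height is None else height
    g = math.ceil(math.sqrt(target_n))
    cx = np.minimum((table.x / w * g).astype(int), g - 1)
    cy = np.minimum((table.y / h * g).astype(int), g - 1)
    cell = cx * g + cy

    rng = np.random.default_rng(seed)
    order = np.lexsort((np.arange(table.n), cell))
    # per-cell row queues, shuffled for unbiased within-cell draws
    queues: list[np.ndarray] = []
    for c in np.unique(cell):
        rows = order[np.searchsorted(cell[order], c, side="left"):
                     np.searchsorted(cell[order], c, side="right")]
        queues.append(rng.permutation(rows))

    picked: list[int] = []
    depth = 0
    while len(picked) < target_n:
        progressed = False
        for q in queues:
            if depth < len(q):
                picked.append(int(q[depth]))
                progressed = True
                if len(picked) == target_n:
                    break
        if not progressed:
            break
        depth += 1
    picked_arr = np.sort(np.asarray(picked, dtype=int))  # preserve row order
    return table.take(picked_arr)


def extract_feature_matrix(batch: WsiBatch, spec: SelectionSpec) -> FeatureMatrix:
    """Apply the selection composition and stack features across the batch.

    Order: debris filter, ellipse filter, then per-WSI sampling of the quota
    ``floor(n_nuc / n_wsi)`` — spatially stratified if ``use_distrib``, else
    uniform.  A WSI whose eligible nuclei fall short of its quota contributes
    what it has and a shortfall warning is emitted.
    """
    quota = spec.n_nuc // batch.n_wsi
    if quota < 1:
        raise ValueError(
            f"n_nuc={spec.n_nuc} yields a zero per-WSI quota for {batch.n_wsi} WSIs"
        )
    children = np.random.SeedSequence(spec.seed).spawn(batch.n_wsi)
    blocks: list[np.ndarray] = []
    shortfall = 0
    for k, table in enumerate(batch.tables):
        t = table
        if spec.use_debris_filter:
            t = select_debris(t)
        if spec.intern_tau is not None:
            t = select_intern(t, spec.intern_tau)
        if t.n == 0:
            warnings.warn(
                f"WSI {table.wsi_id}: no eligible nuclei after filtering",
                QcWarning,
                stacklevel=2,
            )
            continue
        wsi_seed = int(children[k].generate_state(1)[0] % (2**31))
        if t.n > quota:
            if spec.use_distrib:
                t = select_distrib(t, quota, wsi_seed)
            else:
                rng = np.random.default_rng(wsi_seed)
                rows = np.sort(rng.choice(t.n, size=quota, replace=False))
                t = t.take(rows)
        shortfall += max(0, quota - t.n)
        blocks.append(t.features)
    if not blocks:
        raise ValueError("no eligible nuclei in the whole batch")
    if shortfall:
        warnings.warn(
            f"batch {batch.pipeline_id}: {shortfall} nuclei short of the "
            f"{quota}-per-WSI quota",
            QcWarning,
            stacklevel=2,
        )
    values = np.vstack(blocks)
    return FeatureMatrix(values=values, feature_ids=default_feature_ids(batch.n_feat))
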