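"""In-memory containers for nuclei-feature data.

A whole-slide image (WSI) is represented by the nuclei its processing
pipeline segmented: one row per nucleus with spatial coordinates, a debris
flag and a vector of scalar morphometric features.  A preparation pipeline
is observed through batches of such WSIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class NucleusTable:
    """Per-nucleus rows for a single WSI.

    Parameters
    ----------
    wsi_id : str
        Identifier of the slide.
    x, y : ndarray of shape (n,)
        Nucleus centroid coordinates in slide units, within
        ``[0, width] x [0, height]``.
    is_debris : ndarray of bool, shape (n,)
        True for segmented objects judged not to be true nuclei.
    features : ndarray of shape (n, n_feat)
        Scalar features per nucleus; all entries finite.
    width, height : float
        Slide dimensions in the same units as the coordinates.
    """

    wsi_id: str
    x: np.ndarray
    y: np.ndarray
    is_debris: np.ndarray
    features: np.ndarray
    width: float
    height: float

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.is_debris = np.asarray(self.is_debris, dtype=bool)
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        n = self.x.shape[0]
        if not (self.y.shape[0] == self.is_debris.shape[0] == n):
            raise ValueError("coordinate/flag arrays must share one length")
        if self.features.shape[0] != n:
            raise ValueError(
                f"feature matrix has {self.features.shape[0]} rows for {n} nuclei"
            )
        if not np.all(np.isfinite(self.features)):
            bad = int(np.argwhere(~np.isfinite(self.features))[0, 0])
            raise ValueError(f"non-finite feature value at row {bad}")

    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def n_feat(self) -> int:
        return self.features.shape[1]

    def take(self, idx: np.ndarray) -> "NucleusTable":
        """Row subset (order of `idx` preserved)."""
        idx = np.asarray(idx)
        return NucleusTable(
            wsi_id=self.wsi_id,
            x=self.x[idx],
            y=self.y[idx],
            is_debris=self.is_debris[idx],
            features=self.features[idx],
            width=self.width,
            height=self.height,
        )


@dataclass
class WsiBatch:
    """A batch of WSIs produced by one preparation pipeline."""

    pipeline_id: str
    tables: list[NucleusTable] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.tables) < 1:
            raise ValueError("a batch needs at least one WSI")
        n_feats = {t.n_feat for t in self.tables}
        if len(n_feats) != 1:
            raise ValueError(f"inconsistent feature counts across WSIs: {n_feats}")

    @property
    def n_wsi(self) -> int:
        return len(self.tables)

    @property
    def n_feat(self) -> int:
        return self.tables[0].n_feat

    @property
    def total_nuclei(self) -> int:
        return sum(t.n for t in self.tables)


@dataclass
class FeatureMatrix:
    """Stacked nucleus-feature values, one row per selected nucleus."""

    values: np.ndarray
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.feature_ids):
            raise ValueError("feature_ids length must match column count")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_feat(self) -> int:
        return self.values.shape[1]


def default_feature_ids(n_feat: int) -> list[str]:
    """Zero-padded feature names ``f_000 ... f_NNN`` used across the package."""
    width = max(3, len(str(n_feat - 1)))
    return [f"f_{i:0{width}d}" for i in range(n_feat)]
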