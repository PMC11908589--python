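"""Synthetic multi-pipeline nuclei-feature cohorts.

Real preparation pipelines differ in sample preparation, coloration and
scanner; downstream this shows up as per-feature distribution shifts in the
nuclei features, spatial clustering at slide edges (centrifugation), and a
fraction of segmented objects that are debris.  This module emulates those
effects on an abstract feature scale so the whole QC chain is testable
without slide images.

Each pipeline profile draws every feature from a two-component mixture of
truncated Gaussians.  A profile is the canonical mixture translated by a
seed-dependent per-feature offset scaled by ``separation``; at separation 0
all profiles share identical laws, and the expected location gap between two
profiles on a feature is ``separation * |z_a - z_b|`` with ``z`` the stored
standard-normal draws.  Truncation is symmetric (±4 sigma around each
component mean) so analytic mixture means are unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import truncnorm

from .data import NucleusTable, WsiBatch

# Canonical per-feature mixture on the abstract feature scale.
_BASE_MEANS = (0.35, 0.65)
_BASE_SDS = (0.08, 0.08)
_BASE_WEIGHTS = (0.6, 0.4)
_TRUNC = 4.0  # symmetric truncation in units of sigma

# Debris objects are mis-segmentations: broader and displaced feature law.
_DEBRIS_SD_FACTOR = 3.0
_DEBRIS_MEAN_OFFSET = 0.3


@dataclass(frozen=True)
class FeatureLaw:
    """Mixture of truncated Gaussians for one feature."""

    means: tuple[float, ...]
    sds: tuple[float, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.weights), 1.0):
            raise ValueError("mixture weights must sum to 1")
        if any(s <= 0 for s in self.sds):
            raise ValueError("mixture standard deviations must be positive")

    @property
    def mean(self) -> float:
        """Analytic mixture mean (truncation is symmetric, so exact)."""
        return float(np.dot(self.weights, self.means))

    def shifted(self, delta: float) -> "FeatureLaw":
        return FeatureLaw(
            means=tuple(m + delta for m in self.means),
            sds=self.sds,
            weights=self.weights,
        )

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.choice(len(self.weights), size=n, p=np.asarray(self.weights))
        out = np.empty(n)
        for c, (mu, sd) in enumerate(zip(self.means, self.sds)):
            mask = comp == c
            k = int(mask.sum())
            if k:
                out[mask] = truncnorm.rvs(
                    -_TRUNC, _TRUNC, loc=mu, scale=sd, size=k, random_state=rng
                )
        return out


@dataclass(frozen=True)
class PipelineProfile:
    """Generative description of one preparation pipeline.

    ``cluster_fraction`` of nuclei are placed in an elliptical annulus hugging
    the slide border (``edge_band`` controls its radial thickness); the rest
    are uniform over the slide.  Debris rows draw their features from a
    widened, displaced version of each feature law.
    """

    pipeline_id: str
    feature_laws: tuple[FeatureLaw, ...]
    cluster_fraction: float = 0.3
    edge_band: float = 0.1
    debris_rate: float = 0.05
    width: float = 1000.0
    height: float = 800.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.debris_rate <= 1.0:
            raise ValueError("debris_rate must be in [0, 1]")
        if not 0.0 <= self.cluster_fraction <= 1.0:
            raise ValueError("cluster_fraction must be in [0, 1]")

    @property
    def n_feat(self) -> int:
        return len(self.feature_laws)

    def debris_law(self, feature: int) -> FeatureLaw:
        law = self.feature_laws[feature]
        return FeatureLaw(
            means=tuple(m + _DEBRIS_MEAN_OFFSET for m in law.means),
            sds=tuple(s * _DEBRIS_SD_FACTOR for s in law.sds),
            weights=law.weights,
        )


def make_pipeline_profile(
    base_seed: int,
    n_feat: int,
    separation: float,
    *,
    pipeline_id: str | None = None,
    cluster_fraction: float = 0.3,
    debris_rate: float = 0.05,
    width: float = 1000.0,
    height: float = 800.0,
) -> PipelineProfile:
    """Create a reproducible pipeline profile.

    The profile's per-feature mixture means are the canonical means shifted by
    ``separation * z_l`` with ``z_l`` standard-normal draws seeded by
    ``base_seed``.  Distinct seeds at separation > 0 therefore yield
    distinguishable pipelines; at separation 0 all profiles coincide.
    """
    if n_feat < 1:
        raise ValueError("n_feat must be >= 1")
    if separation < 0:
        raise ValueError("separation must be non-negative")
    rng = np.random.default_rng(base_seed)
    offsets = rng.standard_normal(n_feat) * separation
    laws = tuple(
        FeatureLaw(
            means=tuple(m + off for m in _BASE_MEANS),
            sds=_BASE_SDS,
            weights=_BASE_WEIGHTS,
        )
        for off in offsets
    )
    return PipelineProfile(
        pipeline_id=pipeline_id or f"pipeline_{base_seed}",
        feature_laws=laws,
        cluster_fraction=cluster_fraction,
        debris_rate=debris_rate,
        width=width,
        height=height,
    )


def inject_shift(
    profile: PipelineProfile, feature_ids: set[int] | list[int], delta: float
) -> PipelineProfile:
    """Translate the listed features' mixture means by ``delta``.

    Emulates a localized preparation drift (e.g. a coloration change moving
    one color feature) while leaving every other law untouched.
    """
    ids = set(int(i) for i in feature_ids)
    bad = [i for i in ids if not 0 <= i < profile.n_feat]
    if bad:
        raise IndexError(f"unknown feature indices: {sorted(bad)}")
    laws = tuple(
        law.shifted(delta) if l in ids else law
        for l, law in enumerate(profile.feature_laws)
    )
    return replace(profile, feature_laws=laws)


def _place_nuclei(
    n: int, profile: PipelineProfile, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Nucleus coordinates: edge-annulus cluster plus uniform background."""
    w, h = profile.width, profile.height
    on_edge = rng.random(n) < profile.cluster_fraction
    x = rng.uniform(0.0, w, size=n)
    y = rng.uniform(0.0, h, size=n)
    k = int(on_edge.sum())
    if k:
        theta = rng.uniform(0.0, 2 * np.pi, size=k)
        r = rng.uniform(1.0 - profile.edge_band, 1.0, size=k)
        x[on_edge] = w / 2 + r * np.cos(theta) * w / 2
        y[on_edge] = h / 2 + r * np.sin(theta) * h / 2
    return np.clip(x, 0.0, w), np.clip(y, 0.0, h)


def generate_wsi(
    profile: PipelineProfile, wsi_id: str, n_nuclei: int, seed
) -> NucleusTable:
    """Generate one slide's nucleus table (seed may be an int or SeedSequence)."""
    rng = np.random.default_rng(seed)
    is_debris = rng.random(n_nuclei) < profile.debris_rate
    x, y = _place_nuclei(n_nuclei, profile, rng)
    feats = np.empty((n_nuclei, profile.n_feat))
    n_deb = int(is_debris.sum())
    n_ok = n_nuclei - n_deb
    for l, law in enumerate(profile.feature_laws):
        if n_ok:
            feats[~is_debris, l] = law.sample(n_ok, rng)
        if n_deb:
            feats[is_debris, l] = profile.debris_law(l).sample(n_deb, rng)
    return NucleusTable(
        wsi_id=wsi_id,
        x=x,
        y=y,
        is_debris=is_debris,
        features=feats,
        width=profile.width,
        height=profile.height,
    )


def generate_batch(
    profile: PipelineProfile, n_wsi: int, nuclei_per_wsi: int, seed: int
) -> WsiBatch:
    """Generate a batch of ``n_wsi`` slides from one pipeline profile."""
    if n_wsi < 1 or nuclei_per_wsi < 1:
        raise ValueError("n_wsi and nuclei_per_wsi must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_wsi)
    tables = [
        generate_wsi(
            profile, f"{profile.pipeline_id}_wsi{k:03d}", nuclei_per_wsi, child
        )
        for k, child in enumerate(children)
    ]
    return WsiBatch(pipeline_id=profile.pipeline_id, tables=tables)


def make_cohort(
    n_pipelines: int,
    n_feat: int,
    separation: float,
    n_wsi: int,
    nuclei_per_wsi: int,
    seed: int,
    **profile_kwargs,
) -> tuple[list[PipelineProfile], list[WsiBatch], list[WsiBatch]]:
    """Profiles plus matched reference/validation batches for each pipeline.

    Reference and validation batches are disjoint draws from the same profile,
    mirroring a 50/50 split of a lab's slides.
    """
    ss = np.random.SeedSequence(seed)
    profile_seeds = ss.generate_state(n_pipelines) % (2**31)
    batch_children = ss.spawn(2 * n_pipelines)
    profiles, refs, vals = [], [], []
    for i in range(n_pipelines):
        prof = make_pipeline_profile(
            int(profile_seeds[i]),
            n_feat,
            separation,
            pipeline_id=f"pipeline_{i + 1}",
            **profile_kwargs,
        )
        profiles.append(prof)
        r_seed = int(batch_children[2 * i].generate_state(1)[0] % (2**31))
        v_seed = int(batch_children[2 * i + 1].generate_state(1)[0] % (2**31))
        refs.append(generate_batch(prof, n_wsi, nuclei_per_wsi, r_seed))
        vals.append(generate_batch(prof, n_wsi, nuclei_per_wsi, v_seed))
    return profiles, refs, vals
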