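# Methods

This note documents the statistical model implemented by `cytoqc`, its
tunable parameters, the synthetic data generator used for validation, the
numerical conventions, and known limitations.

## The representation

A preparation pipeline is observed through batches of WSIs; each WSI
contributes rows of per-nucleus scalar features (the upstream segmentation
and feature extraction are outside the package — feature tables are its
input).  A batch is represented by one normalized histogram per feature:

1. **Nuclei selection** (`selection` module).  Three composable methods
   parameterize which nuclei enter the representation: an *ellipse filter*
   keeping nuclei inside a centred ellipse whose full axes are a fraction
   `τ` of the slide width and height (slide edges carry centrifugation
   clusters prone to segmentation errors); *spatially even sampling*, a
   stratified draw over a `g×g` grid with `g = ⌈√target⌉`, visiting occupied
   cells round-robin so clusters cannot dominate; and a *debris filter*
   dropping rows flagged as non-nuclei.  Filters run before sampling
   (debris → ellipse → sampling) so per-WSI quotas `⌊n_nuc/n_wsi⌋` are met
   from eligible nuclei; shortfalls take what is available, warn, and never
   sample with replacement.  The empty composition (uniform sampling only)
   is legal.
2. **Histograms** (`representation` module).  Each feature column is
   min–max normalized with bounds `(m_l⁻, m_l⁺)` computed over *all*
   reference and validation nuclei jointly, binned on `[0,1]` with `n_bin`
   equal-width half-open bins (last bin closed so the reference maximum is
   countable), and renormalized to sum to 1.  Out-of-range values are
   dropped before renormalization: they shrink in-range mass rather than
   distort the shape, so batches that exceed the calibration range remain
   representable.  Degenerate features (collapsed bounds, or all values out
   of range) become uniform columns with a QC warning — the distance stays
   defined while the anomaly surfaces.  The mapping commutes with feature
   reduction, `f(C·P) = f(C)·P`, which the tests verify on randomized
   inputs by computing both routes.

`n_bin` defaults to 100: fine enough that a 10⁴-nucleus histogram resolves
mixture structure, coarse enough to avoid empty-bin noise at the nucleus
budgets the package targets.

## Distances

Per-feature distances are bounded on [0, 1]:

* **Wasserstein** — 1-Wasserstein between the discrete distributions on the
  bin centers, computed in closed form as the cumulative-sum gap scaled by
  the bin width; its maximum is `(n_bin−1)/n_bin < 1`.
* **Bhattacharyya** — realized in Hellinger form `√(1 − Σ√(f·f′))`; the raw
  `−ln BC` form is unbounded and would break the weighted-distance algebra,
  so the bounded Hellinger variant of the same coefficient is used.
* **Jensen–Shannon** — square root of the base-2 divergence, a metric
  bounded by 1.

The aggregator `g ∈ {max, mean, median}` collapses per-feature distances to
one pipeline distance.  Under `max` the result is carried by a single
feature, which is reported in every distance and QC report; this is the
attribution mechanism that makes alerts actionable.

## Calibration and scoring

Weights `α_i = min_{j≠i} d(R_i, f(φ(V_j))·P_i)` guarantee by construction
that every foreign validation batch satisfies its dissimilarity constraint;
whether each pipeline's *own* validation batch falls inside its weight is
the empirical accuracy `A` (fraction of diagonal constraints met).  Feature
reductions `P_i` are chosen one-versus-all on the stacked, min–max
normalized reference nuclei, by either a chi-squared univariate filter
(lowest p-values kept; undefined p-values rank last; ties broken by
ascending feature index) or greedy mRMR in the quotient form: relevance =
ANOVA F-statistic, redundancy = mean absolute Pearson correlation with the
already-selected set, importance = their quotient (floored at 1e−12).  "No
selection" is the identity reduction and is a first-class configuration.

Scoring returns the signed weighted distance vector, compatibility,
the quality triple `(Q, Qʳ, Qʳ̄)` and, when no tested reference is given,
the compatibility-gated maximum-quality assignment or a new-reference
alert.  Degenerate calibrations raise explicit alerts rather than failing
numerically:

* `α = 0` (two pipelines indistinguishable) is a hard alert;
* `α = 1` (a bounded distance saturating — possible for Hellinger on
  disjoint supports) makes the quality coefficient `α/(1−α)` undefined; it
  is recorded as a saturation alert and such parameter combinations are
  treated as invalid by the search;
* anomalously small weights (below a quarter of the cohort median) are
  flagged, mirroring the near-duplicate-pipeline situation, and
  `merge_references` lets an operator treat such references as one entity:
  their mutual distances are excluded from the weight minimum while
  representations stay separate (histograms are not pooled).

Streams are scored in contiguous, non-overlapping batches of `n_wsi` WSIs;
a trailing remainder is dropped with a warning.

### Strictness of the compatibility gate

One structural property deserves emphasis.  Because `α_j` equals the
*smallest observed* distance from reference `j` to a foreign validation
batch, a fresh batch from that closest foreign pipeline draws its distance
from the very distribution whose sample defined `α_j` — so it falls below
the weight, violating the dissimilarity constraint, with probability near
one half regardless of sample size.  Consequently the compatibility-gated
assignment resolves to a "no compatible reference" alert for a substantial,
cohort-geometry-dependent fraction of perfectly ordinary batches, while
*wrong* assignments essentially never occur and identification by maximum
quality is reliably correct (both rates are recomputed by
`scripts/acceptance.py`).  Operationally the
quality measure, not the binary gate, is the robust monitoring signal; the
gate is a deliberately conservative alarm.

## Parameter search

The 8 searched parameters are `n_wsi`, `n_nuc`, the nuclei-selection
composition, `ω`, `g`, the feature-selection method, `n_sel`, and the seed.
Enumeration conventions: the nuclei-selection axis is the product of the
ellipse options (absent/0.2/0.4) with the even-sampling switch, including
the empty composition (6 values); the feature axis pairs each method with
each finite `n_sel` plus the single no-selection configuration (2×4+1 = 9
effective values from the 2×5 tested configurations).  Under the reference
grid this enumerates 4374 combinations at one seed.

Filtering: step 1 keeps `A = 1`; step 2 keeps the
`min(k1, ⌈5 % · |valid|⌉)` lowest-error combinations (defaults `k1 = 150`;
2860 valid combinations yield 143); step 3 ranks by `T = 1 − E + H`, where
`H(θ)` sums the frequencies of θ's parameter values within the low-error
set, and keeps the top `k2 = 20`; refinement re-validates each survivor
under fresh seeds and keeps only the always-valid ones.  All ties break by
enumeration order.  The error
`E = 1 − min_i min_{j≠i}(D̃_{i,j} − D̃_{i,i})` is computed on the
column-min-max-normalized cross-distance matrix; degenerate columns are
zeroed with a warning.  An empty valid or stable set raises a QC alert —
the reference/validation sets or the processing pipeline should be
reconsidered.

## Synthetic cohorts

The generator stands in for real multi-pipeline corpora, which are
proprietary.  What it emulates, and the defaults chosen once:

* **Feature laws** — each feature is a two-component mixture of truncated
  Gaussians (canonical means 0.35/0.65, σ = 0.08, weights 0.6/0.4 on an
  abstract scale); a pipeline translates all component means of feature `l`
  by `separation · z_l` with `z_l` seed-specific standard-normal draws.
  Truncation is symmetric (±4σ) so analytic mixture means are exact, which
  the moment tests exploit.  Values are left un-normalized; normalization
  happens only in the representation, exercising the out-of-range rule.
* **Spatial structure** — a fraction of nuclei (default 0.3) is placed in
  an elliptical annulus hugging the slide border (radial band 0.9–1.0),
  emulating centrifugation clusters and making the ellipse filter
  consequential; the rest are uniform.
* **Debris** — rows flagged at `debris_rate` (default 0.05) draw features
  from a widened (3σ), displaced (+0.3) law, making the debris filter
  consequential.

What it does **not** emulate: real morphometric feature scales or
correlations (laws are independent across features), scanner-specific
artifacts, within-slide spatial feature gradients, or temporal
autocorrelation of laboratory streams.  Passing tests therefore demonstrate
the correctness and internal consistency of the QC machinery under
controlled distribution shifts — not calibrated performance on any
particular laboratory's data.

Validation problem sizes are deliberately modest (cohorts of 3–4 pipelines,
4–10 WSIs per batch, 250–1000 nuclei per WSI, reduced parameter grids);
they were chosen as the smallest sizes at which the separation structure
dominates sampling noise, and the methods' guarantees (constraints by
construction, commutation, bounds) hold at any size.

## Numerical conventions

* Ellipse semantics: `τ` scales the full axes (semi-axes `τW/2`, `τH/2`).
* Histogram upper edge closed; value exactly at the maximum lands in the
  last bin.
* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence` spawning; identical inputs and seeds are
  bit-reproducible.
* Ties: ascending feature index in selectors and attributions; enumeration
  order in the search; lowest reference index in assignment.
* β defaults to 0.7, balancing the similarity and dissimilarity terms of
  the quality measure; β = 0 (dissimilarity only) and β = 1 (similarity
  only) are supported.

## Limitations

* Histograms are univariate per feature; joint (multivariate) structure is
  invisible to the distance.
* The compatibility gate is conservative by construction (see above); use
  quality trends for routine monitoring.
* Reference merging is an operator decision; the package does not infer
  which references to merge.
* The chi-squared filter uses the non-negative normalized feature totals
  against the binary label, the standard univariate construction for
  continuous non-negative features.
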