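"""Represent two pipelines by feature histograms and measure their distance.

A pipeline batch becomes an n_bin x n_feat column-stochastic matrix: each
feature is min-max normalized with shared reference bounds, binned on [0,1],
and renormalized.  Two batches are compared feature by feature with a
bounded distance (here 1-Wasserstein) and aggregated with max, which names
the single feature carrying the final distance.
"""

import numpy as np

from cytoqc import (
    DistanceSpec, FeatureMatrix, compute_bounds, distribution_distance,
    generate_batch, make_pipeline_profile, to_distribution,
)

ids = [f"f_{i:03d}" for i in range(4)]
pa = make_pipeline_profile(1, 4, separation=0.3, pipeline_id="lab_A")
pb = make_pipeline_profile(2, 4, separation=0.3, pipeline_id="lab_B")

mats = {}
for prof in (pa, pb):
    batch = generate_batch(prof, n_wsi=4, nuclei_per_wsi=800, seed=7)
    mats[prof.pipeline_id] = FeatureMatrix(
        np.vstack([t.features for t in batch.tables]), ids
    )

bounds = compute_bounds(list(mats.values()))
Fa = to_distribution(mats["lab_A"], bounds, n_bin=100)
Fb = to_distribution(mats["lab_B"], bounds, n_bin=100)

res = distribution_distance(Fa, Fb, DistanceSpec("wasserstein", "max"))
print("per-feature distances:", np.round(res.per_feature, 4))
print(f"aggregated distance d = {res.value:.4f}, carried by {res.argmax_feature}")
print("\nThe aggregated distance is the largest per-feature transport cost;")
print("the named feature is where the two preparations differ most.")
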