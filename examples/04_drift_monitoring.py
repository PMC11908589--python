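"""Detect and attribute a preparation drift in a WSI stream.

A mean shift injected into one feature (emulating e.g. a coloration change)
drives the quality measure below its baseline, and — because the max
aggregator is carried by a single feature — the report names the drifted
feature directly.
"""

import numpy as np

from cytoqc import (
    ParamCombination, calibrate, generate_batch, inject_shift, make_cohort,
    score_batch,
)

profiles, refs, vals = make_cohort(3, 8, 0.5, n_wsi=6, nuclei_per_wsi=600,
                                   seed=21)
params = ParamCombination(
    n_wsi=6, n_nuc=1800, intern_tau=None, use_distrib=True,
    omega="wasserstein", aggregator="max", sel_method=None, n_sel="all", seed=3,
)
module = calibrate(refs, vals, params)
drifted_profile = inject_shift(profiles[0], {2}, delta=0.5)
ref_idx = module.reference_ids().index("pipeline_1")

rng = np.random.default_rng(99)
q_base, q_drift, named = [], [], []
for _ in range(10):
    base = generate_batch(profiles[0], 6, 600, seed=int(rng.integers(2**31)))
    bad = generate_batch(drifted_profile, 6, 600,
                         seed=int(rng.integers(2**31)))
    q_base.append(score_batch(base, module,
                              tested_reference="pipeline_1").quality)
    rep = score_batch(bad, module, tested_reference="pipeline_1")
    q_drift.append(rep.quality)
    named.append(rep.argmax_features[ref_idx])

print(f"baseline quality:  mean {np.mean(q_base):.4f}")
print(f"drifted quality:   mean {np.mean(q_drift):.4f}")
print(f"attributed feature per drifted batch: {named}")
print("\nThe quality drop flags the stream; the attribution (f_002 = the")
print("feature whose law was shifted) tells the operator where to look.")
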