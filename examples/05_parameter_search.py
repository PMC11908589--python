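"""Select QC-module parameters by grid search with seed refinement.

The search keeps valid combinations (accuracy 1), the lowest-error fraction
of them, then the top of the frequency-augmented objective T = 1 - E + H,
and finally only the combinations that stay valid across fresh selection
seeds.  The funnel sizes and the retained combination are printed.
"""

from cytoqc import grid_search, make_cohort

_, refs, vals = make_cohort(3, 6, 0.35, n_wsi=5, nuclei_per_wsi=400, seed=42)

grid = {
    "n_wsi": [5],
    "n_nuc": [1000],
    "intern_tau": [None, 0.4],
    "use_distrib": [False, True],
    "omega": ["wasserstein", "bhattacharyya"],
    "aggregator": ["max", "mean"],
    "sel_method": ["chi2"],
    "n_sel": [3, "all"],
}
result = grid_search(
    refs, vals, grid, single_seed=0, refinement_seeds=list(range(1, 6)),
    k1=8, k2=4, error_fraction=0.5,
)
print(f"grid points evaluated: {len(result.records)}")
print(f"valid (A=1):           {len(result.theta_star)}")
print(f"low-error set:         {len(result.omega_set)}")
print(f"objective-filtered:    {len(result.omega_minus)}")
print(f"seed-stable survivors: {len(result.omega_star)}")
print(f"retained combination:  {result.retained.to_dict()}")
print("\nEvery survivor re-validated (accuracy 1) on five fresh selection")
print("seeds; the retained combination heads the stability ranking.")
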