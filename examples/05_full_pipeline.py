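"""Run the complete analysis: three model families on three endpoints.

For each endpoint (ER-alpha affinity, ER-beta affinity, selectivity S) the
pipeline computes descriptors, splits the data with a Kohonen map, and fits
stepwise MLR, a refit of the published equation, factor-selected PLS, and a
repeat-averaged Bayesian-regularized neural network.
"""
from erqsar import PipelineConfig, run_pipeline

config = PipelineConfig(brnn_repeats=10, seed=1)  # 50 repeats in the full setup
manifest = run_pipeline(config)

for endpoint, stage in manifest["endpoints"].items():
    print(f"\n=== {endpoint} (n = {stage['n_compounds']}) ===")
    rep = stage["reports"]
    mlr = rep["mlr"]
    print(f"  stepwise MLR : R2_tr {mlr['r2_train']:.2f}  Q2_te {mlr['q2_test']:.2f}  "
          f"terms {mlr['terms']}")
    ref = rep["published_refit"]
    cmp_tab = rep["published_comparison"]
    flag = "  [deviation > 0.15 flagged]" if cmp_tab["flagged"] else ""
    print(f"  refit eq.    : R2_tr {ref['r2_train']:.2f}  "
          f"(reported {cmp_tab['reported_r2']:.2f}){flag}")
    pls = rep["pls"]
    print(f"  PLS          : {pls['n_factors']} factors  R2_tr {pls['r2_train']:.2f}  "
          f"Q2_te {pls['q2_test']:.2f}  Q2_loo {pls['q2_loo']:.2f}")
    brnn = rep["brnn"]
    print(f"  BRNN         : r_train {brnn['r_train']:.2f}  r_val {brnn['r_validation']:.2f}  "
          f"r_test {brnn['r_test']:.2f}  ({brnn['n_pcs']} PCs, 5 hidden)")

print("\nR2_tr / Q2_te are training determination and external-test predictivity;")
print("the BRNN r values are Pearson correlations of averaged predictions.")
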