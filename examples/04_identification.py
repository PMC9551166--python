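"""Full identification workflow: PCA overview, SIMCA class models, OPLS-DA.

Uses the default collection design (34 flowers, 80 leaves, 7 seeds) with a stratified
60/40 calibration/validation split, 7 cancellation groups for
cross-validation and a 100-permutation internal validation of the OPLS-DA
model.
"""

import tristepir as t

collection = t.generate_dataset(seed=1)          # default 34 / 80 / 7 design
config = t.PipelineConfig(seed=1, n_permutations=100)
result = t.run_identification(collection, config)

print(result.report_frame().to_string(index=False))
o = result.report["oplsda"]
print(f"\nOPLS-DA validation confusion matrix (rows true, cols predicted):")
for row in o["confusion"]:
    print(" ", row)
print(f"permutation R2Y intercept = {o['r2y_intercept']:.3f} (< 0.3 required)")
print(f"permutation Q2Y intercept = {o['q2y_intercept']:.3f} (< 0.05 required)")
print("\nR2X/R2Y describe fit, Q2 predictive power under cross-validation; "
      "RMSEE/RMSECV/RMSEP are the estimation, cross-validation and "
      "prediction errors of the class-membership response.")
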