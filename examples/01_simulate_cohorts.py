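"""Simulate a training-style T-ALL cohort and its qRT-PCR re-measurement.

Builds a 50-patient cohort (22 relapse / 28 CCR) with the five classifier
genes planted at their array fold changes, then re-measures the matrix at
the IL7R cross-assay correlation (r = 0.92) and checks what survives.
"""

import numpy as np

from tallgc import SimulationConfig, emulate_requantification, fold_change, simulate_cohort

cfg = SimulationConfig(seed=1)  # defaults = training-cohort design
cohort = simulate_cohort(cfg)

print(f"cohort: {cohort.expression.shape[0]} genes x {cohort.n} patients")
print(cohort.clinical["label"].value_counts().to_string())
print("\nplanted R/CCR fold changes (configured -> empirical):")
for gene, fold in cfg.planted_genes:
    fc = fold_change(cohort.expression, cohort.clinical["label"], gene)
    print(f"  {gene:8s} {fold:5.2f} -> {fc:5.2f}")

requant = emulate_requantification(cohort.expression, target_r=0.92, seed=2)
x = np.log2(cohort.expression.loc["IL7R"].to_numpy())
y = np.log2(requant.loc["IL7R"].to_numpy())
print(f"\nIL7R array vs re-measured log2 Pearson r: {np.corrcoef(x, y)[0, 1]:.2f}")
print("(the empirical folds wander around the planted values with n=50;")
print(" the re-measured matrix keeps ~0.92 of the per-gene signal)")
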