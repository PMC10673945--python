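"""Phenomap a trial and estimate individualized treatment effects.

Preprocesses the baseline covariates, builds the Gower dissimilarity
matrix, and runs one weighted Cox fit per participant to obtain
individualized log hazard ratios.  With a binary effect modifier planted,
the label distribution should separate carriers from non-carriers.
"""

from scipy.stats import spearmanr

from phenoadapt import (
    apply_preprocess,
    fit_preprocess,
    generate_trial,
    gower_matrix,
    individualized_loghr,
    true_individual_loghr,
)
from phenoadapt.scenarios import planted_hte_config

cfg = planted_hte_config(n_total=1200, seed=4)
ds = generate_trial(cfg)

fit = fit_preprocess(ds, seed=0)
transformed = apply_preprocess(fit, ds)
pmap = gower_matrix(transformed)
print(f"Gower distances: median {float(pmap.D[pmap.D > 0].mean()):.3f}, max {pmap.D.max():.3f}")

labels = individualized_loghr(ds, pmap)
valid = labels.valid()
print(f"labels: {len(valid)} fitted, {labels.n_dropped} dropped (sparse neighborhoods)")

b0 = ds.table.set_index("id").b0.loc[valid.index]
print(f"mean label, carriers: {valid[b0 == 1].mean():+.3f}")
print(f"mean label, non-carriers: {valid[b0 == 0].mean():+.3f}")
truth = true_individual_loghr(cfg, ds).loc[valid.index]
rho = spearmanr(valid, truth).statistic
print(f"Spearman(label, truth) = {rho:.3f} — positive rank recovery of the planted signal")
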