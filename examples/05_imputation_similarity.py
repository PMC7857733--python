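"""Is the solution robust to multiple imputation?  Similarity across
surrogate imputed datasets.

Emulates m = 20 multiply imputed datasets (10% of cells re-drawn from
each variable's empirical distribution), refits the PCA on each,
Procrustes-aligns all loading matrices toward their running average, and
reports pairwise component similarity.
"""

import syndromics as sy

model = sy.PlantedModel(
    n=150, L=sy.planted_loadings(6, 1, 0.8), noise_sd=0.6, seed=8
)
datasets = sy.generate_imputation_surrogates(model, m=20, corruption_fraction=0.1)
tables = [sy.fit_linear_pca(d).loadings.retain(1) for d in datasets]
result = sy.imputation_stability(tables, ndim=1, s_cut_off=0.2)
print(result.summary.round(3).to_string(index=False))
print(
    "\nMean |CC| near 1 and RMSE near 0 across all 190 dataset pairs: the\n"
    "component is insensitive to the imputation noise, so pooling the\n"
    "imputations is safe for this solution."
)
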