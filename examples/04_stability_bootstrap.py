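"""Component stability: bootstrap with Procrustes alignment and BCa CIs.

Resamples subjects with replacement, refits the PCA each time, rotates
every resampled loading matrix onto the parent, and summarizes the
loading distribution plus the similarity of each resample to the parent
component (congruence coefficient, Pearson r, RMSE, Cattell's s).
"""

import syndromics as sy

data = sy.generate(
    sy.PlantedModel(n=150, L=sy.planted_loadings(6, 1, 0.8), noise_sd=0.6, seed=6)
)
solution = sy.fit_linear_pca(data)
result = sy.pc_stability(
    solution,
    data,
    sy.BootstrapConfig(B=500, scheme="balanced", ndim=1, conf=0.95, seed=7),
)
print(result.loadings_frame().round(3).to_string(index=False))
print()
print(result.similarity_summary.round(3).to_string(index=False))
print(
    "\nBootstrap means sit on the parent loadings (unbiased), the BCa 95%\n"
    "intervals are narrow, and the mean |congruence| to the parent is above\n"
    "the 0.9 rule of thumb: PC1 is stable to sampling variation."
)
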