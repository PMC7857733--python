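"""Fit a linear PCA on synthetic planted-structure data.

Generates a 150-subject, 6-variable dataset driven by one latent factor
(population variable-factor correlation 0.8, Gaussian noise), fits a
correlation-matrix PCA, and prints the standardized loadings, VAF, and
communalities.
"""

import numpy as np

import syndromics as sy

model = sy.PlantedModel(
    n=150, L=sy.planted_loadings(v=6, k=1, loading=0.8), noise_sd=0.6, seed=1
)
data = sy.generate(model)
solution = sy.fit_linear_pca(data, center=True, scale=True)

print("VAF (%):", np.round(solution.vaf, 1))
print(solution.loadings.to_frame().round(3).to_string(index=False))
print("Communalities over 1 PC:")
print(sy.communalities(solution.loadings, ndim=1).round(3).to_string())
print(
    "\nPC1 captures the planted factor: every variable loads near the\n"
    "population PCA loading sqrt((0.64*6+0.36)/6) = 0.837, and PC1's VAF\n"
    "far exceeds the remaining components' noise-level shares."
)
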