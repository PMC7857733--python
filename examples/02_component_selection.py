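"""How many components are real?  Permutation test of VAF (permD).

Shuffling every variable independently destroys all correlation while
keeping the marginals, giving a null for each component's variance
share.  Components whose observed VAF exceeds the null are retained.
"""

import syndromics as sy

data = sy.generate(
    sy.PlantedModel(n=150, L=sy.planted_loadings(6, 2, 0.8), noise_sd=0.6, seed=2)
)
solution = sy.fit_linear_pca(data)
result = sy.permut_pc_test(
    solution,
    data,
    sy.PermutationConfig(statistic="VAF", P=1000, ndim=4, seed=3),
)
print(result.to_frame().round(4).to_string(index=False))
print(
    "\nTwo factors were planted: PC1 and PC2 sit at the attainable p-value\n"
    "floor 1/(P+1) ~ 0.001 while PC3 and PC4 are indistinguishable from the\n"
    "permutation null ('Permuted average' and its 95% CI)."
)
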