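# Methods

## Model and estimands

The package analyzes a complete numeric matrix of n subjects by v
outcome variables. The core fit is a linear PCA computed by SVD of the
centered (and, by default, unit-variance-scaled) data, i.e. a PCA of
the correlation matrix, with eigenvalues on the sample-covariance
scale (divisor n − 1). Three derived quantities carry the analysis:

* **Standardized loadings** `A = E · diag(√λ)` (eigenvectors times
  component standard deviations). For scaled data these are exactly the
  Pearson correlations between each variable and each component score,
  so every loading lies in [−1, 1]; for unscaled data the same product
  is divided row-wise by the variables' standard deviations. The
  "√λ" scaling is deliberate: the alternative reading
  `eigenvectors × eigenvalues` does not produce correlation-bounded
  loadings and cannot reproduce correlation-scale loading tables, so it
  is rejected as a transcription artifact.
* **Communalities** `hᵢ = Σ_{j≤ndim} aᵢⱼ²`, the fraction of variable
  i's variance carried by the retained components.
* **VAF** `100 · λⱼ / Σλ`, a component's percentage of total variance.

Every solution is sign-canonicalized at fit time: each component is
flipped so its largest-|loading| entry is positive (ties broken by
lowest variable index, all-zero columns untouched). This is an
arbitrary but deterministic representative of the sign orbit; all
cross-solution comparisons additionally pass through Procrustes
alignment, so the convention never influences a result.

Rank-deficient input is not an error: the solution always carries
k = v components, with zero eigenvalues and zero loadings beyond the
numerical rank.

## Permutation inference

Two schemes generate the null:

* **permD** — every column shuffled independently and concomitantly.
  Destroys all between-variable correlation, preserves every marginal
  exactly. Used for the VAF test (component selection); requesting VAF
  with permV is overridden to permD (with a warning), because shuffling
  a single variable barely perturbs the total variance shares.
* **permV** — one column shuffled at a time, everything else
  bit-identical. Used for variable-contribution tests (loadings and
  communalities).

Each permuted dataset is refit with the parent solution's options. For
loadings under permV, the retained ndim columns of each refit are
Procrustes-rotated toward the parent loadings before the permuted
variable's row enters its null distribution; communalities are
invariant to those indeterminacies (row norms survive any orthogonal
column transform) and are used unrotated, as are permD loadings, whose
two-sided test on |loading| absorbs the sign indeterminacy.

p-values are `p = (q + 1)/(P + 1)` with q the count of null draws at
least as extreme — `null ≥ observed` for VAF and communalities,
`|null| ≥ |observed|` for loadings (component signs are arbitrary, and
a negative loading is as meaningful as a positive one). The attainable
floor is 1/(P + 1): 0.09 at P = 10, ≈0.001 at the default P = 1000.
P = 1000 is the default as a good precision/compute compromise for
typical outcome batteries; 500 is a reasonable lower bound.

Multiple testing is controlled by Benjamini–Hochberg step-up by
default ("none" available). The adjustment pools **all tests performed
by the call**: ndim values for VAF, v for communalities, and the full
ndim × v matrix jointly for loadings. The joint pooling for loadings
is intentional — per-component pooling would understate the number of
simultaneous decisions an analyst actually makes when reading the full
loading table.

The reported null summary is its mean and the empirical two-tailed
percentile interval at α/2 and 1 − α/2 (numpy's linear-interpolation
quantile), matching the two-sided "Lower/Upper CI" columns of the
serialized tables. Replicate RNGs are spawned per permutation from one
seed sequence, so results are reproducible under a fixed seed and
independent of execution order. Permuting n ≤ 2 rows is allowed but
warned about: the null collapses.

## Bootstrap stability

`pc_stability` draws B subject-resamples (default B = 1000) —
*ordinary* (iid with replacement) or *balanced* (a random permutation
of B copies of each subject index, so the pooled resamples contain
every subject exactly B times) — refits the PCA with the parent's
options, and Procrustes-rotates each refit's retained loadings onto
the parent's. The orthogonal Procrustes problem
`argmin_{TᵀT=I} ‖S·T − L‖_F` is solved by the SVD of `SᵀL`;
reflections are permitted because sign reflection is one of the
indeterminacies being corrected, and the rotation is fit jointly on
all retained components so translocation between them is corrected
too.

Resamples that break the fit preconditions (a zero-variance column
under scaling) are rejected and redrawn, with the count reported — a
silent error would bias the distribution, and such resamples carry no
usable correlation information for that variable.

Loading intervals default to **BCa**: bias correction
`z₀ = Φ⁻¹(#{θ* < θ̂}/B)`, acceleration from the skewness of
leave-one-out jackknife refits (each also Procrustes-aligned).
Degenerate cases — constant resample distributions, all resamples on
one side of the estimate, or adjusted quantile levels escaping (0, 1)
— fall back to the plain percentile interval, and the method actually
used is recorded per loading. Communality and similarity summaries use
percentile intervals throughout.

## Similarity indexes

For two loading vectors x, y on the same variables:
congruence `φ = Σxy/√(Σx²Σy²)`; Pearson r; `RMSE = √(Σ(x−y)²/n)`;
and Cattell's s from the 3 × 3 cross-classification of salience
statuses (positive salient if loading > cutoff, negative salient if
< −cutoff, hyperplane otherwise — **strict** inequalities, so a
loading exactly at the cutoff stays in the hyperplane; this changes s
on edge cases and is fixed here for determinism):

```
s = (f11 + f33 − f13 − f31) / (f11 + f33 + f13 + f31 + (f12+f21+f23+f32)/2)
```

The default salience cutoff is 0.1 (the classical hyperplane width);
analyses of real outcome batteries often prefer 0.2. Summary tables
report |φ| and |s| because a component's global sign is meaningless;
r is reported signed; raw pair results keep all signs. r is a weak
matching index when a component's loadings are nearly uniform (its
variance is then noise-dominated) — the examples show this — which is
why φ is the headline index.

`component_similarity` evaluates all m(m−1)/2 pairs of m loading
matrices per component. `imputation_stability` first aligns the m
matrices by iteratively Procrustes-rotating each toward the running
element-wise average until the average moves less than 1e-8 in
Frobenius norm (cap 100 iterations, non-convergence flagged). A
single-pass variant (one rotation toward the initial average) is
available via `iterative=False`; the iterative form is the default
because the average itself changes after rotation, and iterating makes
the result independent of the starting average.

## Synthetic data

`PlantedModel` generates `X = F·Lᵀ + E` with iid standard-normal
scores F (n × k), an orthogonal-column true loading matrix L whose
per-variable implied variances Σⱼ L²ᵢⱼ stay ≤ 1, and iid Gaussian noise
of standard deviation `noise_sd`; columns are then standardized. With
`Σⱼ L²ᵢⱼ + noise_sd² = 1`, L holds the population variable–factor
correlations. The default regime for power and recovery checks is the
one-factor model with loadings 0.8 and noise 0.6 (unit total
variance) at n ≈ 100–150 — a strong, realistic outcome-battery
signal. Note that the *population PCA loading* under this model is
`√((0.64v + 0.36)/v)` (≈0.837 at v = 6), not 0.8: the first component
also captures the isotropic noise share. Parameter-recovery tests
compare against that functional.

`generate_imputation_surrogates` emulates m multiply imputed datasets
by re-drawing a fixed fraction of cells of one generated dataset from
the corresponding variable's empirical distribution. It reproduces the
key structural feature of multiple imputation — datasets that agree on
most cells and differ on a noisy subset — but not imputation-model
bias, between-variable dependence of imputed values, or MAR/MNAR
mechanisms. Passing tests therefore demonstrate correct behavior of
the stability machinery under cell-level perturbation, not the quality
of any imputation model on real data. Only continuous Gaussian
variables are generated; mixed-type data belong to the (out-of-scope)
nonlinear-PCA pathway.

## Numerical choices and degenerate inputs

* Eigenvalue divisor n − 1; scaling by sample standard deviations.
* Scaling a zero-variance variable is an error naming the variable;
  non-numeric cells are parse errors.
* Quantiles everywhere: numpy linear interpolation.
* BH step-up implemented directly (running minimum over ranked
  `p·m/i`), cross-checked in tests against an independent brute-force
  step-up and statsmodels.
* Congruence of a zero-norm vector, Pearson r of a constant vector,
  and s when every variable is hyperplane on both components are
  errors, not NaNs — except inside bootstrap similarity summaries,
  where a degenerate resample yields NaN and is dropped from the
  summary rather than aborting the run.
* Figure rendering is deterministic: SVG hash salt pinned and
  timestamps suppressed, so identical inputs give byte-identical
  files.

## Test problem sizes

The suite exercises the operating characteristics at desk scale:
type-I error of the VAF test on 20 iid-noise datasets (n = 100,
v = 6, P = 500); power and recovery on 20 planted one-factor datasets
(same size) plus one B = 500 bootstrap; interval coverage over 60
replicates at n = 80, B = 100; similarity oracles on 1000 random
pairs. These sizes give stable Monte-Carlo verdicts for strong
planted effects while keeping the full suite fast.

## Known limitations

* Linear PCA only; nonlinear (optimal-scaling) PCA is supported solely
  through the pre-computed loading-table input path.
* No imputation engine and no missingness-mechanism testing; the
  package consumes complete (already-imputed) matrices.
* No parametric eigenvalue tests, parallel analysis, or scree
  heuristics for component selection — the permutation test is the
  single offered criterion.
* BCa acceleration uses subject-level jackknife refits; for very small
  n the acceleration estimate is noisy and the percentile fallback
  triggers more often.
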