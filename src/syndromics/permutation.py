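"""Permutation inference for components and variable contributions.

Two Monte-Carlo permutation schemes generate null distributions for PCA
statistics:

* **permD** — every variable's rows are shuffled independently and
  concomitantly, destroying all between-variable correlation while
  preserving each marginal exactly.  Used for the VAF test (component
  selection: is a component's variance share distinguishable from what
  random data of the same marginals produce?) and optionally for
  loadings/communalities.
* **permV** — a single variable is shuffled at a time, leaving the rest
  of the data intact.  Used for variable-contribution tests (loadings,
  communalities): does this variable contribute to the solution above
  chance?

For loadings under permV each permuted solution is Procrustes-rotated
toward the parent loadings first, so that sign reflection, rotation
indeterminacy and component translocation do not contaminate the null.
Communalities are invariant to those indeterminacies, so no rotation is
applied for them.

p-values follow the standard Monte-Carlo formula p = (q + 1) / (P + 1),
where q counts null draws at least as extreme as the observed statistic;
the attainable floor is therefore 1 / (P + 1).  Loadings are tested
two-sided on |loading| (component signs are arbitrary); VAF and
communalities one-sided.  Multiple testing is controlled with the
Benjamini–Hochberg step-up by default, pooled over every test the call
performs (all ndim x v loading tests jointly).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pca import DataMatrix, PCASolution, _fit_arrays
from .procrustes import rotate_arrays

__all__ = [
    "PermutationConfig",
    "NullDistribution",
    "permute_permD",
    "permute_permV",
    "permutation_pvalue",
    "adjust_pvalues",
    "permut_pc_test",
]

STATISTICS = ("VAF", "s.loadings", "communalities")
METHODS = ("permD", "permV")


@dataclass(frozen=True)
class PermutationConfig:
    """Settings for :func:`permut_pc_test`.

    ``P`` defaults to 1000 (attainable p-value floor ~0.001), a good
    compromise between precision and compute for typical outcome
    batteries.  ``statistic='VAF'`` forces ``method='permD'``: shuffling
    one variable at a time barely moves the total variance shares, so a
    permV VAF null would be degenerate.
    """

    statistic: str = "VAF"
    method: str | None = None  # resolved per statistic: VAF -> permD, else permV
    P: int = 1000
    ndim: int | None = None
    alpha: float = 0.05
    adjust_method: str = "BH"
    seed: int | None = None

    def __post_init__(self):
        if self.statistic not in STATISTICS:
            raise ValueError(f"statistic must be one of {STATISTICS}, got {self.statistic!r}")
        if self.method is not None and self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.P < 1:
            raise ValueError("P must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.adjust_method not in ("BH", "none"):
            raise ValueError("adjust_method must be 'BH' or 'none'")
        if self.statistic == "VAF":
            if self.method == "permV":
                warnings.warn(
                    "statistic='VAF' always uses the permD scheme; "
                    "ignoring method='permV'",
                    UserWarning,
                    stacklevel=2,
                )
            object.__setattr__(self, "method", "permD")
        elif self.method is None:
            object.__setattr__(self, "method", "permV")


@dataclass(frozen=True)
class NullDistribution:
    """Permutation-test result for one statistic.

    ``original`` and the per-test vectors (``q``, ``p_values``, ...) share
    the statistic's natural shape: ``(ndim,)`` for VAF, ``(v,)`` for
    communalities, ``(v, ndim)`` for loadings.  ``null_samples`` prepends
    the permutation axis (length P).
    """

    statistic: str
    method: str
    variables: list[str] | None
    components: list[str] | None
    original: np.ndarray
    null_samples: np.ndarray
    q: np.ndarray
    p_values: np.ndarray
    adjusted_p: np.ndarray
    null_mean: np.ndarray
    null_ci_low: np.ndarray
    null_ci_high: np.ndarray
    alpha: float
    P: int = field(default=0)

    def to_frame(self) -> pd.DataFrame:
        """Long results table: Variable [, Component], Original, Permuted
        average, Lower CI, Upper CI, p value, Adjusted p value."""
        cols = {
            "Original": self.original,
            "Permuted average": self.null_mean,
            "Lower CI": self.null_ci_low,
            "Upper CI": self.null_ci_high,
            "p value": self.p_values,
            "Adjusted p value": self.adjusted_p,
        }
        if self.original.ndim == 1:
            label = "Component" if self.statistic == "VAF" else "Variable"
            names = self.components if self.statistic == "VAF" else self.variables
            frame = pd.DataFrame({label: names} | {k: v for k, v in cols.items()})
            return frame
        v, ndim = self.original.shape
        frame = pd.DataFrame(
            {
                "Variable": np.repeat(self.variables, ndim),
                "Component": self.components * v,
            }
            | {k: val.reshape(-1) for k, val in cols.items()}
        )
        return frame


def permute_permD(data: DataMatrix, rng: np.random.Generator) -> DataMatrix:
    """Shuffle every column independently (marginals preserved exactly)."""
    return DataMatrix(_permD_array(data.values, rng), data.variable_names, data.subject_ids)


def _permD_array(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n, v = X.shape
    out = np.empty_like(X)
    for j in range(v):
        out[:, j] = X[rng.permutation(n), j]
    return out


def permute_permV(data: DataMatrix, variable_index: int, rng: np.random.Generator) -> DataMatrix:
    """Shuffle one column; every other column is returned bit-identical."""
    if not 0 <= variable_index < data.v:
        raise IndexError(
            f"variable_index {variable_index} out of range for {data.v} variables"
        )
    X = data.values.copy()
    X[:, variable_index] = X[rng.permutation(data.n), variable_index]
    return DataMatrix(X, data.variable_names, data.subject_ids)


def permutation_pvalue(
    original: float, null_samples: np.ndarray, two_sided: bool = False
) -> float:
    """Monte-Carlo p-value p = (q + 1) / (P + 1).

    ``q`` counts null draws >= the observed value (one-sided, used for VAF
    and communalities) or with |null| >= |observed| (two-sided, used for
    loadings, whose signs are arbitrary).
    """
    null_samples = np.asarray(null_samples, dtype=float)
    if null_samples.size == 0:
        raise ValueError("empty null distribution")
    if two_sided:
        q = int(np.sum(np.abs(null_samples) >= abs(original)))
    else:
        q = int(np.sum(null_samples >= original))
    return (q + 1) / (null_samples.size + 1)


def adjust_pvalues(p: np.ndarray, method: str = "BH") -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment (or 'none' pass-through)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "none":
        return p.copy()
    if method != "BH":
        raise ValueError(f"unknown adjustment method {method!r}")
    m = p.size
    flat = p.reshape(-1)
    order = np.argsort(flat, kind="stable")
    ranked = flat[order] * m / np.arange(1, m + 1)
    # step-up: running minimum from the largest p downward
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return adjusted.reshape(p.shape)


def _refit(X, solution: PCASolution):
    """Refit with the parent's recorded options; returns (loadings, vaf)."""
    _, _, load, vaf, _, _ = _fit_arrays(X, solution.centered, solution.scaled)
    return load, vaf


def permut_pc_test(
    solution: PCASolution, data: DataMatrix, config: PermutationConfig
) -> NullDistribution:
    """Permutation test of VAF, standardized loadings, or communalities.

    The parent solution's fit options (centering/scaling) are reused for
    every permuted refit.  Reproducible for a fixed ``config.seed``;
    per-replicate generators are spawned from one seed sequence so the
    replicate stream is order-independent.
    """
    X = data.values
    n, v = X.shape
    k = solution.k
    ndim = config.ndim if config.ndim is not None else k
    if not 1 <= ndim <= k:
        raise ValueError(f"ndim must be in [1, {k}], got {ndim}")
    if n <= 2:
        warnings.warn(
            "n <= 2: the permutation null distribution collapses", UserWarning
        )
    P = config.P
    alpha = config.alpha
    parent_load = solution.loadings.values[:, :ndim]
    root = np.random.SeedSequence(config.seed)

    if config.statistic == "VAF":
        original = solution.vaf[:ndim].copy()
        null = np.empty((P, ndim))
        for p_i, ss in enumerate(root.spawn(P)):
            rng = np.random.default_rng(ss)
            _, vaf = _refit(_permD_array(X, rng), solution)
            null[p_i] = vaf[:ndim]
        two_sided = False
        variables, components = None, solution.loadings.components[:ndim]
    elif config.statistic == "communalities":
        original = np.sum(parent_load**2, axis=1)
        null = np.empty((P, v))
        if config.method == "permD":
            for p_i, ss in enumerate(root.spawn(P)):
                rng = np.random.default_rng(ss)
                load, _ = _refit(_permD_array(X, rng), solution)
                null[p_i] = np.sum(load[:, :ndim] ** 2, axis=1)
        else:  # permV: one variable at a time; only that variable's statistic
            for j, ss_var in enumerate(root.spawn(v)):
                for p_i, ss in enumerate(ss_var.spawn(P)):
                    rng = np.random.default_rng(ss)
                    Xp = X.copy()
                    Xp[:, j] = X[rng.permutation(n), j]
                    load, _ = _refit(Xp, solution)
                    null[p_i, j] = np.sum(load[j, :ndim] ** 2)
        two_sided = False
        variables, components = data.variable_names, solution.loadings.components[:ndim]
    else:  # s.loadings
        original = parent_load.copy()
        null = np.empty((P, v, ndim))
        if config.method == "permD":
            # the full permuted dataset is noise; no rotation target is
            # meaningful, and the two-sided |loading| test absorbs the
            # sign indeterminacy
            for p_i, ss in enumerate(root.spawn(P)):
                rng = np.random.default_rng(ss)
                load, _ = _refit(_permD_array(X, rng), solution)
                null[p_i] = load[:, :ndim]
        else:  # permV with Procrustes correction toward the parent
            for j, ss_var in enumerate(root.spawn(v)):
                for p_i, ss in enumerate(ss_var.spawn(P)):
                    rng = np.random.default_rng(ss)
                    Xp = X.copy()
                    Xp[:, j] = X[rng.permutation(n), j]
                    load, _ = _refit(Xp, solution)
                    rotated, _ = rotate_arrays(load[:, :ndim], parent_load)
                    null[p_i, j] = rotated[j]
        two_sided = True
        variables, components = data.variable_names, solution.loadings.components[:ndim]

    if two_sided:
        q = np.sum(np.abs(null) >= np.abs(original)[None], axis=0)
    else:
        q = np.sum(null >= original[None], axis=0)
    p_values = (q + 1) / (P + 1)
    adjusted = adjust_pvalues(p_values, config.adjust_method)
    ci = np.quantile(null, [alpha / 2, 1 - alpha / 2], axis=0)
    return NullDistribution(
        statistic=config.statistic,
        method=config.method,
        variables=variables,
        components=components,
        original=original,
        null_samples=null,
        q=q,
        p_values=p_values,
        adjusted_p=adjusted,
        null_mean=null.mean(axis=0),
        null_ci_low=ci[0],
        null_ci_high=ci[1],
        alpha=alpha,
        P=P,
    )
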