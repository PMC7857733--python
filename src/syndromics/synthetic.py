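"""Synthetic data with planted component structure.

The generator emulates the kind of dataset the rest of the package
analyzes: a complete subjects x variables matrix whose correlation
structure is driven by a small number of orthogonal latent components.
Data are built from the factor model

    X = F @ L' + E,    F ~ N(0, I_k) scores,  E ~ N(0, noise_sd^2) iid,

then each column is standardized to zero mean and unit sample variance.
With ``sum_j L[i, j]^2 + noise_sd^2 = 1`` the entries of L are the
population variable-component correlations, so a fitted PCA's
standardized loadings should recover L (up to the usual sign/rotation
indeterminacies) — the ground truth that parameter-recovery and power
tests rely on.

Only continuous Gaussian variables are generated; mixed-type (ordinal /
nominal) data, as would be handled by nonlinear PCA, are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pca import DataMatrix

__all__ = [
    "PlantedModel",
    "planted_loadings",
    "generate",
    "generate_imputation_surrogates",
]


def planted_loadings(v: int, k: int, loading: float = 0.8) -> np.ndarray:
    """A simple orthogonal v x k loading matrix: variables are split into
    k contiguous blocks, each loading ``loading`` on its own component and
    0 elsewhere."""
    if not 1 <= k <= v:
        raise ValueError("need 1 <= k <= v")
    if not 0 < abs(loading) <= 1:
        raise ValueError("loading magnitude must be in (0, 1]")
    L = np.zeros((v, k))
    for i in range(v):
        L[i, i * k // v] = loading
    return L


@dataclass(frozen=True)
class PlantedModel:
    """Ground truth for one synthetic dataset.

    ``noise_sd`` is the standard deviation of the iid Gaussian noise added
    on top of the common-factor part.  For a one-factor model with all
    loadings 0.8 the natural companion is ``noise_sd = 0.6`` (unit total
    variance), the default regime for the package's power and recovery
    checks.
    """

    n: int
    L: np.ndarray                 # (v, k) true loading matrix, entries in [-1, 1]
    noise_sd: float = 0.6
    seed: int | None = None

    def __post_init__(self):
        L = np.atleast_2d(np.asarray(self.L, dtype=float))
        if self.n < 3:
            raise ValueError("n must be >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if np.any(np.abs(L) > 1):
            raise ValueError("loadings must lie in [-1, 1]")
        G = L.T @ L
        if not np.allclose(G - np.diag(np.diag(G)), 0, atol=1e-10):
            raise ValueError("columns of L must be orthogonal")
        implied = np.sum(L**2, axis=1)
        if np.any(implied > 1 + 1e-9):
            raise ValueError("per-variable implied variance exceeds 1")
        object.__setattr__(self, "L", L)

    @property
    def v(self) -> int:
        return self.L.shape[0]

    @property
    def k(self) -> int:
        return self.L.shape[1]


def _generate_raw(model: PlantedModel, rng: np.random.Generator) -> np.ndarray:
    scores = rng.standard_normal((model.n, model.k))
    noise = rng.standard_normal((model.n, model.v)) * model.noise_sd
    X = scores @ model.L.T + noise
    X = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):  # astronomically unlikely for Gaussian draws
        raise RuntimeError("degenerate draw: zero-variance column")
    return X / sd


def generate(model: PlantedModel) -> DataMatrix:
    """One standardized dataset from the planted model (deterministic under seed)."""
    rng = np.random.default_rng(np.random.SeedSequence(model.seed))
    X = _generate_raw(model, rng)
    names = [f"V{i + 1}" for i in range(model.v)]
    return DataMatrix(X, names, [f"S{i + 1}" for i in range(model.n)])


def generate_imputation_surrogates(
    model: PlantedModel, m: int, corruption_fraction: float
) -> list[DataMatrix]:
    """m noisy copies of one dataset, emulating multiply imputed data.

    A multiple-imputation run yields m complete datasets that agree on the
    observed cells and differ on the imputed ones.  As a surrogate, each
    copy re-draws the given fraction of cells from that variable's
    empirical distribution (sampling the column with replacement), leaving
    the remaining cells identical across copies.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    if not 0 <= corruption_fraction <= 0.5:
        raise ValueError("corruption_fraction must be in [0, 0.5]")
    root = np.random.SeedSequence(model.seed)
    base_ss, corrupt_ss = root.spawn(2)
    X = _generate_raw(model, np.random.default_rng(base_ss))
    n, v = X.shape
    n_cells = int(round(corruption_fraction * n * v))
    names = [f"V{i + 1}" for i in range(v)]
    ids = [f"S{i + 1}" for i in range(n)]
    out = []
    for ss in corrupt_ss.spawn(m):
        rng = np.random.default_rng(ss)
        Xi = X.copy()
        if n_cells:
            flat = rng.choice(n * v, size=n_cells, replace=False)
            rows, cols = np.unravel_index(flat, (n, v))
            Xi[rows, cols] = X[rng.integers(0, n, size=n_cells), cols]
        out.append(DataMatrix(Xi, names, ids))
    return out
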