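"""Bootstrap stability of PCA loadings, communalities, and components.

Component stability asks how sensitive a PCA solution is to sampling
variation: a robust disease pattern should survive resampling of the
subjects.  The workflow here:

1. Draw B resamples of the subjects (ordinary bootstrap by default, or
   balanced, where each subject appears exactly B times across the
   pooled resamples).
2. Refit the PCA on each resample with the parent solution's options and
   Procrustes-rotate the retained loadings toward the parent to remove
   sign reflection, rotation indeterminacy, and component translocation.
3. Summarize: per-loading means and confidence intervals (bias-corrected
   and accelerated, BCa, by default, with an automatic percentile
   fallback in degenerate cases), communality means with percentile
   intervals, and per-component similarity of every resample to the
   parent (congruence, r, RMSE, Cattell's s).

Resamples that violate the PCA preconditions (a zero-variance column
under scaling) are rejected and redrawn; the rejection count is
reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .pca import DataMatrix, LoadingsTable, PCASolution, ZeroVarianceError, _fit_arrays
from .procrustes import rotate_arrays
from .similarity import (
    DEFAULT_S_CUTOFF,
    congruence_coefficient,
    pearson_similarity,
    rmse_similarity,
    s_index,
    _resolve_metrics,
)

__all__ = [
    "BootstrapConfig",
    "BootstrapDistribution",
    "BcaInterval",
    "bootstrap_indices",
    "boot_pca_sample",
    "bca_ci",
    "pc_stability",
]

SCHEMES = ("ordinary", "balanced")


@dataclass(frozen=True)
class BootstrapConfig:
    """Settings for :func:`pc_stability`.

    ``B`` defaults to 1000 resamples; ``conf`` is the two-sided
    confidence level for every interval; ``ci_type`` selects BCa
    (default) or plain percentile intervals for the loadings
    (communalities always use percentile intervals).
    """

    B: int = 1000
    scheme: str = "ordinary"
    ndim: int | None = None
    conf: float = 0.95
    ci_type: str = "bca"
    seed: int | None = None
    similarity_metrics: tuple[str, ...] | str = "all"
    s_cut_off: float = DEFAULT_S_CUTOFF
    test_similarity: bool = True
    max_redraws: int = 1000

    def __post_init__(self):
        if self.B < 2:
            raise ValueError("B must be >= 2")
        if not 0 < self.conf < 1:
            raise ValueError("conf must be in (0, 1)")
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        if self.ci_type not in ("bca", "percentile"):
            raise ValueError("ci_type must be 'bca' or 'percentile'")


class BcaInterval(NamedTuple):
    """(low, high) bounds plus the method actually used ('bca' or 'percentile')."""

    low: float
    high: float
    method: str


@dataclass(frozen=True)
class BootstrapDistribution:
    """B Procrustes-aligned resampled loading matrices and their summaries."""

    rotated_loadings: np.ndarray       # (B, v, ndim)
    variables: list[str]
    components: list[str]
    original: np.ndarray               # (v, ndim) parent retained loadings
    loading_mean: np.ndarray           # (v, ndim)
    loading_ci_low: np.ndarray
    loading_ci_high: np.ndarray
    ci_method_used: np.ndarray         # (v, ndim) of 'bca'/'percentile'
    communality_mean: np.ndarray       # (v,)
    communality_ci_low: np.ndarray
    communality_ci_high: np.ndarray
    similarity: pd.DataFrame | None    # raw per-resample per-PC index values
    similarity_summary: pd.DataFrame | None
    conf: float
    rejected_resamples: int = 0

    def loadings_frame(self) -> pd.DataFrame:
        v, ndim = self.loading_mean.shape
        return pd.DataFrame(
            {
                "Variable": np.repeat(self.variables, ndim),
                "Component": self.components * v,
                "Original": self.original.reshape(-1),
                "Mean": self.loading_mean.reshape(-1),
                "Lower CI": self.loading_ci_low.reshape(-1),
                "Upper CI": self.loading_ci_high.reshape(-1),
                "CI method": self.ci_method_used.reshape(-1),
            }
        )

    def communalities_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Variable": self.variables,
                "Mean": self.communality_mean,
                "Lower CI": self.communality_ci_low,
                "Upper CI": self.communality_ci_high,
            }
        )


def bootstrap_indices(
    n: int, B: int, scheme: str = "ordinary", rng: np.random.Generator | None = None
) -> np.ndarray:
    """B resample index vectors of length n.

    ``ordinary``: each vector is n iid draws with replacement.
    ``balanced``: the pooled B x n indices contain every subject exactly
    B times (a random permutation of B copies of 0..n-1, cut into B
    vectors), which reduces simulation variance of bootstrap means.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}")
    rng = np.random.default_rng() if rng is None else rng
    if scheme == "ordinary":
        return rng.integers(0, n, size=(B, n))
    pooled = rng.permutation(np.repeat(np.arange(n), B))
    return pooled.reshape(B, n)


def boot_pca_sample(
    data: DataMatrix,
    indices: np.ndarray,
    parent: PCASolution,
    ndim: int | None = None,
) -> LoadingsTable:
    """Refit the PCA on one resample and align it to the parent.

    The refit uses the parent's centering/scaling options; the retained
    ``ndim`` loading columns are Procrustes-rotated toward the parent's
    retained loadings.

    Raises
    ------
    ZeroVarianceError
        If the resample leaves a variable constant under scaling (callers
        in :func:`pc_stability` reject and redraw such resamples).
    """
    ndim = parent.k if ndim is None else ndim
    X = data.values[np.asarray(indices)]
    _, _, load, _, _, _ = _fit_arrays(X, parent.centered, parent.scaled, data.variable_names)
    target = parent.loadings.values[:, :ndim]
    rotated, _ = rotate_arrays(load[:, :ndim], target)
    return LoadingsTable(
        parent.loadings.variables, parent.loadings.components[:ndim], rotated
    )


def bca_ci(
    samples: np.ndarray,
    original: float,
    jackknife_stats: np.ndarray | None,
    conf: float = 0.95,
) -> BcaInterval:
    """Bias-corrected and accelerated bootstrap confidence interval.

    The bias correction z0 comes from the fraction of bootstrap samples
    below the original estimate; the acceleration from the skewness of
    leave-one-out jackknife replicates (``jackknife_stats=None`` forces
    acceleration 0).  Degenerate cases — constant samples, all samples on
    one side of the original, or adjusted quantile levels falling outside
    (0, 1) — fall back to the plain percentile interval, recorded in the
    returned ``method`` field.
    """
    samples = np.asarray(samples, dtype=float).reshape(-1)
    if samples.size == 0:
        raise ValueError("empty bootstrap sample")
    alpha = 1 - conf
    lo_q, hi_q = alpha / 2, 1 - alpha / 2
    percentile = BcaInterval(
        float(np.quantile(samples, lo_q)), float(np.quantile(samples, hi_q)), "percentile"
    )
    if np.ptp(samples) == 0:
        return percentile
    frac_below = np.mean(samples < original)
    if frac_below == 0 or frac_below == 1:
        return percentile
    z0 = ndtri(frac_below)
    if jackknife_stats is None:
        a = 0.0
    else:
        jack = np.asarray(jackknife_stats, dtype=float).reshape(-1)
        d = jack.mean() - jack
        denom = 6.0 * np.sum(d**2) ** 1.5
        a = float(np.sum(d**3) / denom) if denom > 0 else 0.0
    z_lo, z_hi = ndtri(lo_q), ndtri(hi_q)
    levels = []
    for z in (z_lo, z_hi):
        denom = 1 - a * (z0 + z)
        if denom <= 0:
            return percentile
        levels.append(float(ndtr(z0 + (z0 + z) / denom)))
    if not 0 < levels[0] < levels[1] < 1:
        return percentile
    return BcaInterval(
        float(np.quantile(samples, levels[0])), float(np.quantile(samples, levels[1])), "bca"
    )


_INDEX_FUNCS = {
    "cc_index": congruence_coefficient,
    "r_correlation": pearson_similarity,
    "rmse": rmse_similarity,
}


def _similarity_to_parent(
    rotated: np.ndarray, parent: np.ndarray, metrics, s_cut_off: float
) -> pd.DataFrame:
    """Per-resample, per-PC similarity of rotated loadings to the parent."""
    B, v, ndim = rotated.shape
    rows = []
    for b in range(B):
        for j in range(ndim):
            row = {"resample": b, "PC": f"PC{j + 1}"}
            for metric in metrics:
                try:
                    if metric == "s_index":
                        val = s_index(rotated[b, :, j], parent[:, j], s_cut_off)
                    else:
                        val = _INDEX_FUNCS[metric](rotated[b, :, j], parent[:, j])
                except ValueError:
                    val = np.nan
                row[metric] = val
            rows.append(row)
    return pd.DataFrame(rows)


def pc_stability(
    solution: PCASolution, data: DataMatrix, config: BootstrapConfig | None = None
) -> BootstrapDistribution:
    """Bootstrap the PCA and summarize loading/communality/component stability.

    Reproducible for a fixed ``config.seed``.  Returns per-loading means
    and BCa (or percentile) intervals, communality means with percentile
    intervals, and — when ``config.test_similarity`` — the distribution
    of each similarity index between every aligned resample and the
    parent, summarized by mean, SD, and two-tailed percentile interval.
    """
    config = BootstrapConfig() if config is None else config
    ndim = solution.k if config.ndim is None else config.ndim
    if not 1 <= ndim <= solution.k:
        raise ValueError(f"ndim must be in [1, {solution.k}], got {ndim}")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n, v = data.n, data.v
    B = config.B
    parent = solution.loadings.values[:, :ndim]
    indices = bootstrap_indices(n, B, config.scheme, rng)
    rotated = np.empty((B, v, ndim))
    rejected = 0
    for b in range(B):
        idx = indices[b]
        for _ in range(config.max_redraws + 1):
            try:
                rotated[b] = boot_pca_sample(data, idx, solution, ndim).values
                break
            except ZeroVarianceError:
                rejected += 1
                idx = rng.integers(0, n, size=n)
        else:
            raise RuntimeError(
                f"could not draw a valid resample after {config.max_redraws} redraws"
            )
    if rejected:
        warnings.warn(
            f"{rejected} degenerate resample(s) (zero-variance variable) "
            "were rejected and redrawn",
            UserWarning,
        )

    alpha = 1 - config.conf
    # loadings: BCa (with leave-one-out jackknife acceleration) or percentile
    jack = None
    if config.ci_type == "bca":
        jack = np.empty((n, v, ndim))
        keep = np.ones(n, dtype=bool)
        ok = True
        for i in range(n):
            keep[i] = False
            try:
                jack[i] = boot_pca_sample(
                    data, np.flatnonzero(keep), solution, ndim
                ).values
            except ZeroVarianceError:
                ok = False
                break
            finally:
                keep[i] = True
        if not ok:
            warnings.warn(
                "jackknife for BCa acceleration failed on a zero-variance "
                "leave-one-out subset; using percentile intervals",
                UserWarning,
            )
            jack = None
    ci_low = np.empty((v, ndim))
    ci_high = np.empty((v, ndim))
    ci_method = np.empty((v, ndim), dtype=object)
    for i in range(v):
        for j in range(ndim):
            if config.ci_type == "bca":
                res = bca_ci(
                    rotated[:, i, j],
                    parent[i, j],
                    jack[:, i, j] if jack is not None else None,
                    config.conf,
                )
            else:
                lo, hi = np.quantile(rotated[:, i, j], [alpha / 2, 1 - alpha / 2])
                res = BcaInterval(float(lo), float(hi), "percentile")
            ci_low[i, j], ci_high[i, j], ci_method[i, j] = res

    # communalities: rotation-invariant row norms; percentile intervals
    comm = np.sum(rotated**2, axis=2)  # (B, v)
    comm_ci = np.quantile(comm, [alpha / 2, 1 - alpha / 2], axis=0)

    similarity = similarity_summary = None
    if config.test_similarity:
        metrics = _resolve_metrics(config.similarity_metrics)
        similarity = _similarity_to_parent(rotated, parent, metrics, config.s_cut_off)
        rows = []
        for j in range(ndim):
            sub = similarity[similarity["PC"] == f"PC{j + 1}"]
            row: dict[str, object] = {"PC": f"PC{j + 1}"}
            for metric in metrics:
                x = sub[metric].to_numpy(dtype=float)
                x = np.abs(x) if metric in ("cc_index", "s_index") else x
                x = x[np.isfinite(x)]
                row[f"{metric}_mean"] = float(np.mean(x))
                row[f"{metric}_sd"] = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
                lo, hi = np.quantile(x, [alpha / 2, 1 - alpha / 2])
                row[f"{metric}_low"] = float(lo)
                row[f"{metric}_high"] = float(hi)
            rows.append(row)
        similarity_summary = pd.DataFrame(rows)

    return BootstrapDistribution(
        rotated_loadings=rotated,
        variables=solution.loadings.variables,
        components=solution.loadings.components[:ndim],
        original=parent.copy(),
        loading_mean=rotated.mean(axis=0),
        loading_ci_low=ci_low,
        loading_ci_high=ci_high,
        ci_method_used=ci_method,
        communality_mean=comm.mean(axis=0),
        communality_ci_low=comm_ci[0],
        communality_ci_high=comm_ci[1],
        similarity=similarity,
        similarity_summary=similarity_summary,
        conf=config.conf,
        rejected_resamples=rejected,
    )
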