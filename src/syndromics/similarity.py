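"""Factor-matching (component similarity) indexes.

Four classical indexes quantify how alike two component loading vectors
x and y over the same variables are:

* **Congruence coefficient (CC, Tucker's phi)** — the cosine similarity
  sum(x_i y_i) / sqrt(sum(x_i^2) sum(y_i^2)).  |CC| >= 0.9 is the usual
  rule of thumb for a good component match.
* **Pearson r** — the correlation of the two loading vectors; identical
  to CC when both vectors are mean-centered.
* **RMSE** — sqrt(mean((x_i - y_i)^2)); 0 means a perfect match.
* **Cattell's s** — built from the cross-classification of each
  variable's salience status on the two components: positive salient
  (loading > cutoff), hyperplane (|loading| <= cutoff), or negative
  salient (loading < -cutoff).  With f_ij the joint counts (index
  1 = PS, 2 = H, 3 = NS; rows = component 1, columns = component 2):

      s = (f11 + f33 - f13 - f31)
          / (f11 + f33 + f13 + f31 + (f12 + f21 + f23 + f32) / 2)

Because a component's overall sign is arbitrary, summary tables report
|CC| and |s| (signed values are kept in the raw pair results; r is
reported signed).  Salience uses strict inequality: a loading exactly at
the cutoff stays in the hyperplane.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pca import LoadingsTable
from .procrustes import rotate_arrays

__all__ = [
    "CrossClassificationTable",
    "SimilarityResult",
    "SimilarityCollection",
    "congruence_coefficient",
    "pearson_similarity",
    "rmse_similarity",
    "cross_classify",
    "s_index",
    "component_similarity",
    "imputation_stability",
    "METRICS",
]

METRICS = ("cc_index", "r_correlation", "rmse", "s_index")

DEFAULT_S_CUTOFF = 0.1  # Cattell's classical hyperplane half-width


@dataclass(frozen=True)
class CrossClassificationTable:
    """3x3 joint counts of salience statuses across two components.

    ``f[i][j]`` with i = status on component 1, j = status on component 2,
    status order (PS, H, NS).
    """

    counts: np.ndarray  # (3, 3) integer

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (3, 3) or np.any(counts < 0):
            raise ValueError("cross-classification must be a non-negative 3x3 table")
        object.__setattr__(self, "counts", counts)

    @property
    def n_variables(self) -> int:
        return int(self.counts.sum())

    def f(self, i: int, j: int) -> int:
        """1-based cell accessor: f(1, 3) is the PS/NS count."""
        return int(self.counts[i - 1, j - 1])


@dataclass(frozen=True)
class SimilarityResult:
    """All requested indexes for one pair of components (signed values)."""

    pair: tuple[str, str]
    component: str
    cc: float | None = None
    r: float | None = None
    rmse: float | None = None
    s: float | None = None
    s_cut_off: float | None = None


@dataclass(frozen=True)
class SimilarityCollection:
    """Pairwise similarity over m loading matrices.

    ``summary`` holds per-PC mean and SD of each index over all
    m(m-1)/2 pairs, with |CC| and |s| (r signed) following the reporting
    convention for sign-indeterminate components.
    """

    pair_results: list[SimilarityResult]
    summary: pd.DataFrame
    converged: bool = True

    def to_frame(self) -> pd.DataFrame:
        return self.summary.copy()


def congruence_coefficient(x: np.ndarray, y: np.ndarray) -> float:
    """Tucker's congruence coefficient (cosine similarity) of two loading vectors."""
    x, y = _check_pair(x, y)
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("congruence coefficient undefined for a zero-norm vector")
    return float(x @ y / (nx * ny))


def pearson_similarity(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of two loading vectors."""
    x, y = _check_pair(x, y)
    if x.size < 2:
        raise ValueError("Pearson similarity needs vectors of length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson similarity undefined for a constant vector")
    return float(np.corrcoef(x, y)[0, 1])


def rmse_similarity(x: np.ndarray, y: np.ndarray) -> float:
    """Root mean squared difference of two loading vectors (0 iff identical)."""
    x, y = _check_pair(x, y)
    return float(np.sqrt(np.mean((x - y) ** 2)))


def _check_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size == 0:
        raise ValueError("empty loading vectors")
    return x, y


def _status(x: np.ndarray, cutoff: float) -> np.ndarray:
    """0 = positive salient, 1 = hyperplane, 2 = negative salient (strict)."""
    return np.where(x > cutoff, 0, np.where(x < -cutoff, 2, 1))


def cross_classify(x: np.ndarray, y: np.ndarray, cutoff: float) -> CrossClassificationTable:
    """Joint salience-status counts of shared variables on two components.

    Strict inequalities: a loading exactly equal to +-cutoff is
    hyperplane.
    """
    x, y = _check_pair(x, y)
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    sx, sy = _status(x, cutoff), _status(y, cutoff)
    counts = np.zeros((3, 3), dtype=int)
    np.add.at(counts, (sx, sy), 1)
    return CrossClassificationTable(counts)


def s_index(x: np.ndarray, y: np.ndarray, cutoff: float = DEFAULT_S_CUTOFF) -> float:
    """Cattell's s: salient-pattern agreement of two components in [-1, 1]."""
    t = cross_classify(x, y, cutoff).counts
    agree = t[0, 0] + t[2, 2]
    disagree = t[0, 2] + t[2, 0]
    half = t[0, 1] + t[1, 0] + t[1, 2] + t[2, 1]
    denom = agree + disagree + half / 2
    if denom == 0:
        raise ValueError(
            "s index undefined: every variable is in the hyperplane on both components"
        )
    return float((agree - disagree) / denom)


def _pair_result(
    xs: np.ndarray,
    ys: np.ndarray,
    pair: tuple[str, str],
    component: str,
    metrics: tuple[str, ...],
    s_cut_off: float,
) -> SimilarityResult:
    return SimilarityResult(
        pair=pair,
        component=component,
        cc=congruence_coefficient(xs, ys) if "cc_index" in metrics else None,
        r=pearson_similarity(xs, ys) if "r_correlation" in metrics else None,
        rmse=rmse_similarity(xs, ys) if "rmse" in metrics else None,
        s=s_index(xs, ys, s_cut_off) if "s_index" in metrics else None,
        s_cut_off=s_cut_off if "s_index" in metrics else None,
    )


def _resolve_metrics(metrics) -> tuple[str, ...]:
    if metrics is None or metrics == "all" or metrics == ("all",) or metrics == ["all"]:
        return METRICS
    if isinstance(metrics, str):
        metrics = (metrics,)
    bad = [m for m in metrics if m not in METRICS]
    if bad:
        raise ValueError(f"unknown similarity metrics {bad}; choose from {METRICS}")
    return tuple(metrics)


_SUMMARY_COLUMNS = {"cc_index": "cc", "r_correlation": "r", "rmse": "rmse", "s_index": "s"}


def _summarize(
    pair_results: list[SimilarityResult],
    components: list[str],
    metrics: tuple[str, ...],
) -> pd.DataFrame:
    """Per-PC mean and SD per index; |cc| and |s| per the sign convention."""
    rows = []
    for pc in components:
        row: dict[str, object] = {"PC": pc}
        vals = [r for r in pair_results if r.component == pc]
        for metric in metrics:
            attr = _SUMMARY_COLUMNS[metric]
            x = np.array([getattr(r, attr) for r in vals], dtype=float)
            if metric in ("cc_index", "s_index"):
                x = np.abs(x)
            row[f"{metric}_mean"] = float(x.mean())
            row[f"{metric}_sd"] = float(x.std(ddof=1)) if x.size > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def component_similarity(
    matrices: list[LoadingsTable],
    metrics="all",
    ndim: int | None = None,
    s_cut_off: float = DEFAULT_S_CUTOFF,
    labels: list[str] | None = None,
) -> SimilarityCollection:
    """All pairwise per-PC similarity indexes over m loading matrices.

    Variables are matched by name against the first matrix; every
    unordered pair (m(m-1)/2 of them) is evaluated per component.
    """
    if len(matrices) < 2:
        raise ValueError("need at least 2 loading matrices")
    metrics = _resolve_metrics(metrics)
    ref = matrices[0]
    ndim = min(m.k for m in matrices) if ndim is None else ndim
    if any(ndim > m.k for m in matrices):
        raise ValueError(f"ndim={ndim} exceeds the components of some matrix")
    aligned = [m.align_variables(ref.variables).values[:, :ndim] for m in matrices]
    if labels is None:
        labels = [f"M{i + 1}" for i in range(len(matrices))]
    components = ref.components[:ndim]
    pair_results = []
    for (a, b) in itertools.combinations(range(len(aligned)), 2):
        for jc, pc in enumerate(components):
            pair_results.append(
                _pair_result(
                    aligned[a][:, jc],
                    aligned[b][:, jc],
                    (labels[a], labels[b]),
                    pc,
                    metrics,
                    s_cut_off,
                )
            )
    return SimilarityCollection(pair_results, _summarize(pair_results, components, metrics))


def imputation_stability(
    matrices: list[LoadingsTable],
    ndim: int | None = None,
    metrics="all",
    s_cut_off: float = DEFAULT_S_CUTOFF,
    iterative: bool = True,
    tol: float = 1e-8,
    max_iter: int = 100,
    labels: list[str] | None = None,
) -> SimilarityCollection:
    """Similarity of loading solutions from multiply imputed datasets.

    Each matrix is Procrustes-rotated toward the element-wise average of
    the set, removing the PCA indeterminacies before comparison.  With
    ``iterative=True`` (default) the rotate-and-average step is repeated
    until the average stops moving (Frobenius change < ``tol``), which
    makes the alignment independent of the initial average; a single pass
    is available with ``iterative=False``.  Similarity indexes are then
    computed over all pairs of the aligned matrices.
    """
    if len(matrices) < 2:
        raise ValueError("need at least 2 loading matrices")
    ref = matrices[0]
    ndim = min(m.k for m in matrices) if ndim is None else ndim
    stack = np.stack(
        [m.align_variables(ref.variables).values[:, :ndim] for m in matrices]
    )
    converged = True
    target = stack.mean(axis=0)
    rotated = stack
    n_iter = 1 if not iterative else max_iter
    for _ in range(n_iter):
        rotated = np.stack([rotate_arrays(m, target)[0] for m in stack])
        new_target = rotated.mean(axis=0)
        change = np.linalg.norm(new_target - target)
        target = new_target
        if change < tol:
            break
    else:
        if iterative:
            converged = False
            warnings.warn(
                f"rotation toward the average did not converge in {max_iter} "
                "iterations; returning the last iterate",
                UserWarning,
            )
    aligned = [
        LoadingsTable(ref.variables, ref.components[:ndim], rotated[i])
        for i in range(rotated.shape[0])
    ]
    result = component_similarity(
        aligned, metrics=metrics, ndim=ndim, s_cut_off=s_cut_off, labels=labels
    )
    return SimilarityCollection(result.pair_results, result.summary, converged=converged)
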