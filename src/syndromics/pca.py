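"""Linear PCA core: standardized loadings, communalities, and VAF.

Syndromic analysis treats the leading principal components of a
subjects x variables outcome matrix as proxies for multivariate disease
patterns.  This module fits a linear PCA (via SVD, ``prcomp``-style with
an ``n - 1`` eigenvalue divisor) and derives the quantities the rest of
the package reasons about:

* **standardized loadings** — correlation-scale weights of each variable
  on each component.  For a PCA of centered, unit-variance data the
  loading of variable *i* on component *j* equals the Pearson correlation
  between the variable and the component score.
* **communalities** — the sum of squared loadings of one variable across
  the retained components: the fraction of that variable's variance the
  retained solution explains.
* **VAF** — variance accounted for, each eigenvalue as a percentage of
  the total variance.

A deterministic sign convention (the largest-magnitude loading of every
component is made positive) is applied at fit time so that resampled
solutions are comparable before any Procrustes alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DataMatrix",
    "LoadingsTable",
    "PCASolution",
    "ZeroVarianceError",
    "fit_linear_pca",
    "stand_loadings",
    "communalities",
    "canonicalize_signs",
]


class ZeroVarianceError(ValueError):
    """Raised when unit-variance scaling is requested for a constant variable."""

    def __init__(self, variables: Sequence[str]):
        self.variables = list(variables)
        super().__init__(
            "cannot scale zero-variance variable(s): " + ", ".join(self.variables)
        )


def _component_labels(k: int) -> list[str]:
    return [f"PC{j + 1}" for j in range(k)]


@dataclass(frozen=True)
class DataMatrix:
    """A complete numeric subjects x variables matrix.

    Completeness is a precondition: missing-value handling (e.g. multiple
    imputation) happens upstream, and this container rejects NaN/inf.
    """

    values: np.ndarray
    variable_names: list[str]
    subject_ids: list = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, v = values.shape
        if v < 2:
            raise ValueError(f"need at least 2 variables, got {v}")
        if n < 3:
            raise ValueError(f"need at least 3 subjects, got {n}")
        if not np.all(np.isfinite(values)):
            raise ValueError("data matrix contains missing or non-finite entries")
        names = [str(x) for x in self.variable_names]
        if len(names) != v:
            raise ValueError("variable_names length does not match matrix width")
        if len(set(names)) != v:
            raise ValueError("variable_names must be unique")
        ids = self.subject_ids
        ids = list(range(n)) if ids is None else list(ids)
        if len(ids) != n:
            raise ValueError("subject_ids length does not match matrix height")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "variable_names", names)
        object.__setattr__(self, "subject_ids", ids)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def v(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, id_column: str | None = None) -> "DataMatrix":
        """Build from a DataFrame; ``id_column`` (if given) supplies subject ids."""
        frame = frame.copy()
        ids = None
        if id_column is not None:
            ids = frame.pop(id_column).tolist()
        try:
            values = frame.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric cell in data matrix: {exc}") from exc
        return cls(values, list(frame.columns), ids)

    def to_frame(self, id_column: str | None = None) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.variable_names)
        if id_column is not None:
            # ids serialize as strings so readers can tell them from data
            frame.insert(0, id_column, [str(s) for s in self.subject_ids])
        return frame

    def take(self, indices: np.ndarray) -> "DataMatrix":
        """Row-resample (used by the bootstrap)."""
        indices = np.asarray(indices)
        return DataMatrix(
            self.values[indices],
            self.variable_names,
            [self.subject_ids[i] for i in indices],
        )


@dataclass(frozen=True)
class LoadingsTable:
    """Variables x components matrix of standardized loadings.

    Serialized form follows the package-wide layout: a first column
    literally named ``Variables`` followed by ``PC1``..``PCk`` columns,
    so externally computed solutions (including nonlinear PCA) can be
    fed to the visualization and similarity functions.
    """

    variables: list[str]
    components: list[str]
    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("loadings must be a 2-D matrix")
        if values.shape != (len(self.variables), len(self.components)):
            raise ValueError("loadings shape does not match labels")
        if not np.all(np.isfinite(values)):
            raise ValueError("loadings must be finite")
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("variable names must be unique")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "variables", [str(x) for x in self.variables])
        object.__setattr__(self, "components", [str(x) for x in self.components])

    @property
    def k(self) -> int:
        return self.values.shape[1]

    @property
    def v(self) -> int:
        return self.values.shape[0]

    def column(self, component: str | int) -> np.ndarray:
        """Loading vector of one component, by label ("PC2") or 0-based index."""
        if isinstance(component, str):
            j = self.components.index(component)
        else:
            j = component
        return self.values[:, j]

    def retain(self, ndim: int | Sequence[int]) -> "LoadingsTable":
        """Keep the first ``ndim`` components, or an explicit list of
        1-based component numbers (e.g. ``[3, 4, 5]``)."""
        if np.isscalar(ndim):
            if not 1 <= int(ndim) <= self.k:
                raise ValueError(f"ndim must be in [1, {self.k}], got {ndim}")
            idx = list(range(int(ndim)))
        else:
            idx = [int(j) - 1 for j in ndim]
            if any(j < 0 or j >= self.k for j in idx):
                raise ValueError(f"component numbers out of range 1..{self.k}: {ndim}")
        return LoadingsTable(
            self.variables,
            [self.components[j] for j in idx],
            self.values[:, idx],
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "LoadingsTable":
        if len(frame.columns) == 0 or frame.columns[0] != "Variables":
            raise ValueError(
                "first column of a loadings table must be named 'Variables', "
                f"got {frame.columns[0]!r}" if len(frame.columns) else "empty table"
            )
        pcs = list(frame.columns[1:])
        if not pcs:
            raise ValueError("no component columns")
        expected = _component_labels(len(pcs))
        if pcs != expected:
            raise ValueError(
                f"component columns must be contiguous {expected}, got {pcs}"
            )
        values = frame[pcs].to_numpy(dtype=float)
        return cls(list(frame["Variables"].astype(str)), pcs, values)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.components)
        frame.insert(0, "Variables", self.variables)
        return frame

    def align_variables(self, variables: Sequence[str]) -> "LoadingsTable":
        """Reorder rows to a reference variable ordering (matched by name)."""
        missing = [v for v in variables if v not in self.variables]
        extra = [v for v in self.variables if v not in variables]
        if missing or extra:
            raise ValueError(
                f"variable mismatch: missing {missing or 'none'}, unmatched {extra or 'none'}"
            )
        order = [self.variables.index(v) for v in variables]
        return LoadingsTable(list(variables), self.components, self.values[order])


@dataclass(frozen=True)
class PCASolution:
    """A fitted linear PCA.

    ``eigenvalues`` use the sample-covariance (n - 1) divisor.  ``sdev``
    records the per-variable standard deviations of the training data; it
    is the row scaling used for standardized loadings when the PCA was run
    on unscaled data.  ``center``/``scaled`` record the fit options so that
    resampling replicates can refit with identical specifications.
    """

    eigenvalues: np.ndarray          # (k,), non-increasing, >= 0
    eigenvectors: np.ndarray         # (v, k), orthonormal columns (up to rank)
    loadings: LoadingsTable          # standardized, sign-canonicalized
    vaf: np.ndarray                  # (k,), percent, sums to 100
    scaled: bool
    centered: bool
    sdev: np.ndarray                 # (v,) training-data standard deviations
    mean: np.ndarray                 # (v,) training-data means (0 if not centered)
    n: int                           # subjects used in the fit

    @property
    def k(self) -> int:
        return self.eigenvalues.shape[0]

    def transform(self, data: DataMatrix) -> np.ndarray:
        """Component scores of ``data`` under this solution's preprocessing."""
        X = data.values - self.mean
        if self.scaled:
            X = X / self.sdev
        return X @ self.eigenvectors


def _canon_signs(loadings: np.ndarray) -> np.ndarray:
    """Per-column sign flips making the max-|loading| entry positive.

    Ties broken by lowest row index; all-zero columns keep sign +1.
    """
    v, k = loadings.shape
    signs = np.ones(k)
    absval = np.abs(loadings)
    for j in range(k):
        i = int(np.argmax(absval[:, j]))  # argmax returns the first maximum
        if loadings[i, j] < 0:
            signs[j] = -1.0
    return signs


def _fit_arrays(
    X: np.ndarray, center: bool, scale: bool, variable_names: Sequence[str] | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """SVD path shared by the public fit and the resampling loops.

    Returns (eigenvalues, eigenvectors, loadings, vaf, sdev, mean), all as
    plain arrays with k = v components (zero-padded beyond the rank).
    """
    X = np.asarray(X, dtype=float)
    n, v = X.shape
    mean = X.mean(axis=0) if center else np.zeros(v)
    Xc = X - mean
    sdev = X.std(axis=0, ddof=1)
    if scale:
        zero = np.flatnonzero(sdev == 0)
        if zero.size:
            names = (
                [variable_names[i] for i in zero]
                if variable_names is not None
                else [f"column {i}" for i in zero]
            )
            raise ZeroVarianceError(names)
        Xw = Xc / sdev
    else:
        Xw = Xc
    U, s, Vt = np.linalg.svd(Xw, full_matrices=False)
    eig = s**2 / (n - 1)
    # components beyond the numerical rank: eigenvalue 0, zero loadings
    tol = (s[0] * max(n, v) * np.finfo(float).eps) if s.size and s[0] > 0 else 0.0
    eig[s <= tol] = 0.0
    eigvec = Vt.T
    if eigvec.shape[1] < v:  # n < v: pad so the solution always has v components
        pad = v - eigvec.shape[1]
        eigvec = np.hstack([eigvec, np.zeros((v, pad))])
        eig = np.concatenate([eig, np.zeros(pad)])
    loadings = eigvec * np.sqrt(eig)
    if not scale:
        zero = np.flatnonzero(sdev == 0)
        if zero.size:
            names = (
                [variable_names[i] for i in zero]
                if variable_names is not None
                else [f"column {i}" for i in zero]
            )
            raise ZeroVarianceError(names)
        loadings = loadings / sdev[:, None]
    total = eig.sum()
    if total == 0:
        raise ValueError("data matrix has no variance; PCA undefined")
    vaf = 100.0 * eig / total
    signs = _canon_signs(loadings)
    return eig, eigvec * signs, loadings * signs, vaf, sdev, mean


def fit_linear_pca(data: DataMatrix, center: bool = True, scale: bool = True) -> PCASolution:
    """Fit a linear PCA on a complete data matrix.

    Parameters
    ----------
    data:
        Complete subjects x variables matrix.
    center:
        Subtract per-variable means (default True).
    scale:
        Divide by per-variable sample standard deviations, i.e. run the
        PCA on the correlation matrix (default True, the usual choice for
        outcome batteries on heterogeneous scales).

    Returns
    -------
    PCASolution
        Always with ``k = v`` components; eigenvalues use the n - 1
        divisor, loadings are standardized (correlation-scale) and
        sign-canonicalized, VAF is in percent and sums to 100.

    Raises
    ------
    ZeroVarianceError
        If ``scale`` is requested and some variable is constant.
    """
    eig, eigvec, load, vaf, sdev, mean = _fit_arrays(
        data.values, center, scale, data.variable_names
    )
    table = LoadingsTable(data.variable_names, _component_labels(load.shape[1]), load)
    return PCASolution(
        eigenvalues=eig,
        eigenvectors=eigvec,
        loadings=table,
        vaf=vaf,
        scaled=scale,
        centered=center,
        sdev=sdev,
        mean=mean,
        n=data.n,
    )


def stand_loadings(solution: PCASolution) -> LoadingsTable:
    """Standardized loadings of a fitted solution.

    For a PCA of unit-variance data the loadings are
    ``eigenvectors @ diag(sqrt(eigenvalues))`` — the component standard
    deviations — which places every loading on the correlation scale.
    For a PCA of unscaled data the same product is divided row-wise by
    the variables' standard deviations ``S``.
    """
    load = solution.eigenvectors * np.sqrt(solution.eigenvalues)
    if not solution.scaled:
        if np.any(solution.sdev == 0):
            names = [
                solution.loadings.variables[i]
                for i in np.flatnonzero(solution.sdev == 0)
            ]
            raise ZeroVarianceError(names)
        load = load / solution.sdev[:, None]
    return LoadingsTable(
        solution.loadings.variables, solution.loadings.components, load
    )


def communalities(loadings: LoadingsTable, ndim: int) -> pd.Series:
    """Sum of squared loadings of each variable over the first ``ndim`` PCs.

    For a scaled PCA each communality lies in [0, 1]: the fraction of the
    variable's variance explained by the retained components.
    """
    if not 1 <= ndim <= loadings.k:
        raise ValueError(f"ndim must be in [1, {loadings.k}], got {ndim}")
    h = np.sum(loadings.values[:, :ndim] ** 2, axis=1)
    return pd.Series(h, index=loadings.variables, name="communality")


def canonicalize_signs(loadings: LoadingsTable) -> LoadingsTable:
    """Flip component signs so each column's max-|loading| entry is positive.

    Idempotent; ties broken by lowest variable index; all-zero columns are
    left unchanged.  Sign reflection is one of the PCA indeterminacies:
    this fixes a deterministic representative without changing magnitudes,
    eigenvalues, VAF, or communalities.
    """
    signs = _canon_signs(loadings.values)
    return LoadingsTable(loadings.variables, loadings.components, loadings.values * signs)
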