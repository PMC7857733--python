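"""Orthogonal Procrustes alignment of loading matrices.

Resampled PCA solutions are only comparable to their parent after
correcting three indeterminacies: sign reflection, rotation
indeterminacy, and component translocation (swaps of neighbouring
components with similar eigenvalues).  All three are orthogonal
transformations of the loading matrix, so the least-squares orthogonal
Procrustes rotation of a resampled matrix toward the parent (target)
matrix removes them jointly.  Reflections are allowed (the full
orthogonal group): no scaling, no translation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pca import LoadingsTable

__all__ = ["RotationResult", "procrustes_rotate", "rotate_arrays"]


@dataclass(frozen=True)
class RotationResult:
    """Outcome of one Procrustes alignment."""

    rotated: LoadingsTable       # source @ rotation, on the target's variable order
    rotation: np.ndarray         # (k, k) orthogonal matrix
    residual: float              # ||rotated - target||_F


def rotate_arrays(source: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Array fast path: returns ``(source @ T, T)`` with T = argmin ||source T - target||_F.

    T = U V' from the SVD of source' target (the classical solution); the
    determinant of T is unconstrained, so reflections are permitted.
    """
    M = source.T @ target
    U, _, Vt = np.linalg.svd(M)
    T = U @ Vt
    return source @ T, T


def procrustes_rotate(source: LoadingsTable, target: LoadingsTable) -> RotationResult:
    """Rotate ``source`` loadings toward ``target`` in the least-squares sense.

    Variables are matched by name (rows reordered as needed); both tables
    must have the same number of components.

    Raises
    ------
    ValueError
        On unmatched variable names or component-count mismatch.
    """
    if source.k != target.k:
        raise ValueError(
            f"component count mismatch: source has {source.k}, target has {target.k}"
        )
    source = source.align_variables(target.variables)
    rotated, T = rotate_arrays(source.values, target.values)
    residual = float(np.linalg.norm(rotated - target.values))
    return RotationResult(
        rotated=LoadingsTable(target.variables, target.components, rotated),
        rotation=T,
        residual=residual,
    )
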