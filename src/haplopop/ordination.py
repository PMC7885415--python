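r"""Principal Coordinates Analysis of population genetic distance matrices.

Classical (metric) multidimensional scaling via Gower double-centering:
given a symmetric dissimilarity matrix :math:`D` (here typically the
pairwise population :math:`\Phi_{ST}` matrix, with negative estimates
clamped to zero), form :math:`B = -\tfrac12 J (D \circ D) J` with
:math:`J = I - \tfrac1n \mathbf{1}\mathbf{1}^T`, take the symmetric
eigendecomposition, and scale eigenvectors by the square root of their
(positive) eigenvalues. Percent variance explained is reported per axis
relative to the sum of positive eigenvalues only; negative eigenvalues
(non-Euclidean residue) are excluded. Eigenvector sign is fixed by
making the largest-magnitude loading of each axis positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .differentiation import DistanceMatrix, FstMatrix

__all__ = ["PcoaResult", "pcoa"]

_EIG_TOL = 1e-9


@dataclass(frozen=True)
class PcoaResult:
    labels: tuple[str, ...]
    coordinates: np.ndarray  # populations x positive axes, decreasing eigenvalue
    eigenvalues: np.ndarray  # all eigenvalues, decreasing
    percent_variance: np.ndarray  # per positive axis, sums to 100

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


def _as_matrix(
    distance: FstMatrix | DistanceMatrix | np.ndarray,
) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(distance, FstMatrix):
        return np.array(distance.values, dtype=float), distance.populations
    if isinstance(distance, DistanceMatrix):
        return np.array(distance.values, dtype=float), distance.labels
    arr = np.asarray(distance, dtype=float)
    return arr, tuple(str(i) for i in range(arr.shape[0]))


def pcoa(
    distance: FstMatrix | DistanceMatrix | np.ndarray,
    clamp_negative: bool = True,
    linearize: bool = False,
) -> PcoaResult:
    """Principal coordinates of a symmetric distance/differentiation matrix.

    Parameters
    ----------
    distance
        Symmetric matrix with zero diagonal; asymmetry beyond 1e-8 is an
        error.
    clamp_negative
        Replace negative entries (possible for pairwise Phi_ST) by zero
        before embedding.
    linearize
        Use Slatkin's transform ``d / (1 - d)`` of the differentiation
        values instead of the raw values.
    """
    d, labels = _as_matrix(distance)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance must be a square matrix")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix is asymmetric beyond tolerance")
    d = (d + d.T) / 2.0
    if clamp_negative:
        d = np.maximum(d, 0.0)
    if linearize:
        with np.errstate(divide="raise"):
            d = d / (1.0 - d)
    np.fill_diagonal(d, 0.0)

    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d * d) @ j
    eigvals, eigvecs = scipy.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    scale = max(abs(eigvals[0]), 1.0) if n else 1.0
    positive = eigvals > _EIG_TOL * scale
    pos_vals = eigvals[positive]
    coords = eigvecs[:, positive] * np.sqrt(pos_vals)
    # eigenvector sign is arbitrary; pin it for reproducibility
    for a in range(coords.shape[1]):
        col = coords[:, a]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, a] = -col
    pct = 100.0 * pos_vals / pos_vals.sum() if pos_vals.size else pos_vals
    return PcoaResult(labels, coords, eigvals, pct)
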