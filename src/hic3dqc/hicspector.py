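"""Spectral reproducibility score from normalized-Laplacian eigenvectors.

For contact map W with degrees D_ii = sum_j W_ij the Laplacian is
L = D - W, normalized as D^-1/2 L D^-1/2. The distance between two maps
is the sum of Euclidean distances between their r leading (smallest
eigenvalue) unit eigenvectors, sign-aligned, and the score is the linear
rescale 1 - S_d / (r * sqrt(2)) clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .errors import UndefinedScoreError, ValidationError
from .matrix_io import ContactMatrix, marginals

__all__ = [
    "SpectralDecomposition",
    "normalized_laplacian",
    "leading_eigenvectors",
    "spector_distance",
    "spector_score",
]

DEFAULT_R = 20


@dataclass
class SpectralDecomposition:
    support: np.ndarray  # original bin indices retained (non-zero degree)
    laplacian: np.ndarray  # un-normalized L = D - W on the support
    l_norm: np.ndarray  # D^-1/2 L D^-1/2
    eigenvalues: np.ndarray | None = None
    eigenvectors: np.ndarray | None = None  # columns, ascending eigenvalue


def _restrict(m: ContactMatrix, support: np.ndarray) -> np.ndarray:
    return m.counts[np.ix_(support, support)]


def _offdiag_degrees(m: ContactMatrix) -> np.ndarray:
    """Node degrees of the contact graph; self-contacts are not edges."""
    return marginals(m) - np.diag(m.counts)


def normalized_laplacian(m: ContactMatrix, support: np.ndarray | None = None) -> SpectralDecomposition:
    """Normalized Laplacian on the non-zero-degree support of ``m``
    (or an explicitly supplied common support).

    The contact graph is treated as loop-free: diagonal counts are
    dropped, so the normalized Laplacian has unit diagonal.
    """
    if support is None:
        support = np.flatnonzero(_offdiag_degrees(m) > 0)
    support = np.asarray(support, dtype=int)
    if support.size == 0:
        raise UndefinedScoreError("empty support: matrix has no non-zero-degree bin")
    W = _restrict(m, support).copy()
    np.fill_diagonal(W, 0.0)
    d = W.sum(axis=1)
    if np.any(d <= 0):
        raise ValidationError("support contains zero-degree bins")
    L = np.diag(d) - W
    inv_sqrt = 1.0 / np.sqrt(d)
    l_norm = L * np.outer(inv_sqrt, inv_sqrt)
    return SpectralDecomposition(support=support, laplacian=L, l_norm=l_norm)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-absolute-value entry is positive."""
    out = vectors.copy()
    for j in range(out.shape[1]):
        idx = int(np.argmax(np.abs(out[:, j])))
        if out[idx, j] < 0:
            out[:, j] = -out[:, j]
    return out


def leading_eigenvectors(sd: SpectralDecomposition, r: int) -> np.ndarray:
    """Unit eigenvectors of the r smallest eigenvalues, ascending, with
    the deterministic sign convention applied. Columns of the result."""
    n = sd.l_norm.shape[0]
    if r > n:
        raise ValidationError(f"r={r} exceeds support size {n}")
    if r < 1:
        raise ValidationError("r must be >= 1")
    vals, vecs = linalg.eigh(sd.l_norm, subset_by_index=[0, r - 1])
    vecs = _fix_signs(vecs)
    sd.eigenvalues = vals
    sd.eigenvectors = vecs
    return vecs


def spector_distance(a: ContactMatrix, b: ContactMatrix, r: int = DEFAULT_R) -> float:
    """S_d = sum over i < r of the Euclidean distance between the i-th
    sign-aligned eigenvector pair, on the common support."""
    if a.counts.shape != b.counts.shape:
        raise ValidationError("matrices must have the same shape")
    support = np.flatnonzero((_offdiag_degrees(a) > 0) & (_offdiag_degrees(b) > 0))
    if support.size == 0:
        raise UndefinedScoreError("no common non-zero-degree support")
    if r > support.size:
        raise ValidationError(f"r={r} exceeds common support size {support.size}")
    va = leading_eigenvectors(normalized_laplacian(a, support), r)
    vb = leading_eigenvectors(normalized_laplacian(b, support), r)
    # eigenvector sign remains arbitrary under near-ties; align per index
    dist = 0.0
    for i in range(r):
        dist += min(
            float(np.linalg.norm(va[:, i] - vb[:, i])),
            float(np.linalg.norm(va[:, i] + vb[:, i])),
        )
    return dist


def spector_score(a: ContactMatrix, b: ContactMatrix, r: int = DEFAULT_R) -> float:
    """Linear rescale of S_d to [0, 1]: 1 - S_d / (r * sqrt(2))."""
    dist = spector_distance(a, b, r)
    return float(np.clip(1.0 - dist / (r * np.sqrt(2.0)), 0.0, 1.0))
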