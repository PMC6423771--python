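"""Random-walk concordance score between two contact maps.

Each map is sqrt-normalized (entry divided by the square root of the
product of its two bins' marginals), row-normalized to a transition
matrix, and raised to the walk length t. The per-t distance is the L1
norm of the difference of the smoothed maps divided by the average
number of non-zero-marginal nodes; scores combine distances over t by
trapezoidal area under the curve and map to 1 - distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import split_rng
from .errors import UndefinedScoreError, ValidationError
from .matrix_io import ContactMatrix, marginals, total_interactions
from .resampling import downsample

__all__ = [
    "TransitionMatrix",
    "sqrt_normalize",
    "random_walk_smooth",
    "disco_distance",
    "disco_score",
]

DEFAULT_T_VALUES = (3,)


@dataclass
class TransitionMatrix:
    values: np.ndarray  # P^t, rows with non-zero degree sum to 1
    t: int


def sqrt_normalize(m: ContactMatrix) -> np.ndarray:
    """out[i,j] = m[i,j] / sqrt(d_i * d_j); zero-marginal bins give zero
    rows/columns. Invariant to global positive scaling of m."""
    d = marginals(m)
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
    return m.counts * np.outer(inv_sqrt, inv_sqrt)


def _row_stochastic(norm: np.ndarray) -> np.ndarray:
    rowsums = norm.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(rowsums[:, None] > 0, norm / np.where(rowsums[:, None] > 0, rowsums[:, None], 1.0), 0.0)
    return P


def random_walk_smooth(norm: np.ndarray, t: int) -> TransitionMatrix:
    """Row-normalize to a stochastic matrix P and return P^t."""
    if t < 1:
        raise ValidationError("t must be >= 1")
    P = _row_stochastic(np.asarray(norm, dtype=float))
    return TransitionMatrix(np.linalg.matrix_power(P, t), t)


def _nnz_nodes(m: ContactMatrix) -> int:
    return int(np.count_nonzero(marginals(m)))


def disco_distance(a: ContactMatrix, b: ContactMatrix, t_values=DEFAULT_T_VALUES) -> float:
    """Combined normalized L1 distance in [0, 2].

    For each t, d_t = ||P_a^t - P_b^t||_1 / mean(nnz_nodes(a),
    nnz_nodes(b)); a single t yields d_t itself, several t the
    trapezoidal AUC over t divided by the t-span.
    """
    if a.counts.shape != b.counts.shape:
        raise ValidationError("matrices must have the same shape")
    t_values = sorted(int(t) for t in t_values)
    if not t_values:
        raise ValidationError("t_values must be non-empty")
    denom = (_nnz_nodes(a) + _nnz_nodes(b)) / 2.0
    if denom == 0:
        raise UndefinedScoreError("both matrices are empty")
    Pa = _row_stochastic(sqrt_normalize(a))
    Pb = _row_stochastic(sqrt_normalize(b))
    dists = []
    Qa, Qb = np.eye(a.n_bins), np.eye(b.n_bins)
    power = 0
    for t in t_values:
        while power < t:
            Qa = Qa @ Pa
            Qb = Qb @ Pb
            power += 1
        dists.append(float(np.abs(Qa - Qb).sum()) / denom)
    if len(t_values) == 1:
        return dists[0]
    auc = np.trapezoid(dists, t_values)
    return float(auc / (t_values[-1] - t_values[0]))


def disco_score(a: ContactMatrix, b: ContactMatrix, t_values=DEFAULT_T_VALUES, seed=None) -> float:
    """Reproducibility = 1 - combined distance, in [-1, 1].

    When totals differ the higher-coverage map is first downsampled to
    match the other (coverage matching), using ``seed``.
    """
    na, nb = total_interactions(a), total_interactions(b)
    if a.is_raw and b.is_raw and na != nb:
        r1, _ = split_rng(seed, 2)
        if na > nb:
            a = downsample(a, int(nb), r1)
        else:
            b = downsample(b, int(na), r1)
    return 1.0 - disco_distance(a, b, t_values)
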