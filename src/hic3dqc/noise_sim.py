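"""Noise model for Hi-C contact matrices.

Two "pure noise" matrices are derived from a real matrix M:

* G, genomic-distance noise: at each bin offset D the entries of M with
  |i - k| = D are shuffled among themselves, stratified by the product
  of the two bins' marginals (strata of 100 cells, cut from the sorted
  marginal-product order). G preserves the per-offset sums of M exactly
  while destroying domain structure.
* R, random-ligation noise: N unit interactions are drawn by picking two
  bins independently with probability proportional to their marginals,
  where N is M's total interaction count.

Noisy matrices are mixtures: counts sampled uniformly without
replacement from M, G and R at a target ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import rng_from, split_rng, upper_values, symmetric_from_upper
from .errors import ValidationError
from .matrix_io import ContactMatrix, marginals, total_interactions

__all__ = [
    "NoiseMix",
    "genomic_distance_noise",
    "random_ligation_noise",
    "mix_matrices",
    "noise_ladder",
    "DEFAULT_NOISE_LEVELS",
]

DEFAULT_NOISE_LEVELS = (0.05, 0.10, 0.15, 0.20, 0.30, 0.40, 0.50)


@dataclass
class NoiseMix:
    """Mixture recipe: total counts, noise proportion, G share of noise."""

    total_counts: int
    noise_fraction: float
    g_share: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.noise_fraction <= 1.0):
            raise ValidationError("noise_fraction must be in [0, 1]")
        if not (0.0 <= self.g_share <= 1.0):
            raise ValidationError("g_share must be in [0, 1]")
        if self.total_counts < 0:
            raise ValidationError("total_counts must be >= 0")


def genomic_distance_noise(m: ContactMatrix, stratum_size: int = 100, seed=None) -> ContactMatrix:
    """Shuffle matrix entries within each offset D = |i - k|, stratified
    by marginal product into consecutive groups of ``stratum_size``."""
    if not m.is_raw:
        raise ValidationError("noise generation requires a raw count matrix")
    if stratum_size < 1:
        raise ValidationError("stratum_size must be >= 1")
    rng = rng_from(seed)
    n = m.n_bins
    marg = marginals(m)
    out = np.zeros_like(m.counts)
    for d in range(n):
        i = np.arange(n - d)
        k = i + d
        vals = m.counts[i, k].copy()
        prod = marg[i] * marg[k]
        order = np.argsort(prod, kind="stable")
        shuffled = vals.copy()
        for start in range(0, len(order), stratum_size):
            grp = order[start : start + stratum_size]
            shuffled[grp] = vals[grp][rng.permutation(len(grp))]
        out[i, k] = shuffled
        out[k, i] = shuffled
    return ContactMatrix(m.chrom, m.resolution, out, is_raw=True)


def random_ligation_noise(m: ContactMatrix, seed=None) -> ContactMatrix:
    """Draw N bin pairs, each bin independently with probability
    proportional to its marginal; aggregate into a symmetric matrix."""
    if not m.is_raw:
        raise ValidationError("noise generation requires a raw count matrix")
    n_total = total_interactions(m)
    if n_total <= 0:
        raise ValidationError("cannot build random-ligation noise from an all-zero matrix")
    rng = rng_from(seed)
    marg = marginals(m)
    p = marg / marg.sum()
    n = m.n_bins
    draws_i = rng.choice(n, size=int(n_total), p=p)
    draws_k = rng.choice(n, size=int(n_total), p=p)
    lo = np.minimum(draws_i, draws_k)
    hi = np.maximum(draws_i, draws_k)
    flat = np.bincount(lo * n + hi, minlength=n * n).reshape(n, n).astype(float)
    counts = flat + flat.T - np.diag(np.diag(flat))
    return ContactMatrix(m.chrom, m.resolution, counts, is_raw=True)


def _largest_remainder(c: int, fractions: np.ndarray) -> np.ndarray:
    """Integer apportionment of c among sources, exact total."""
    raw = c * fractions
    base = np.floor(raw).astype(np.int64)
    short = int(c - base.sum())
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base


def _sample_counts(source: ContactMatrix, n: int, rng) -> np.ndarray:
    """Draw n unit interactions uniformly without replacement from a
    source matrix; returns upper-triangle count vector."""
    colors = np.round(upper_values(source.counts)).astype(np.int64)
    return rng.multivariate_hypergeometric(colors, int(n)).astype(float)


def mix_matrices(m: ContactMatrix, G: ContactMatrix, R: ContactMatrix, mix: NoiseMix, seed=None) -> ContactMatrix:
    """Combine counts from the real matrix and the two noise matrices.

    Exactly ``round(c*(1-f))`` counts come from m, ``round(c*f*g_share)``
    from G and the remainder from R (largest-remainder rounding, so the
    three parts always sum to c). Each part is drawn uniformly without
    replacement from its source's individual interactions.
    """
    if not (m.counts.shape == G.counts.shape == R.counts.shape):
        raise ValidationError("matrices must share a shape")
    c = int(mix.total_counts)
    f, g = mix.noise_fraction, mix.g_share
    wants = _largest_remainder(c, np.array([1.0 - f, f * g, f * (1.0 - g)]))
    sources = {"real": m, "G": G, "R": R}
    for (name, src), w in zip(sources.items(), wants):
        if w > total_interactions(src):
            raise ValidationError(
                f"requested {w} counts from source {name} but it holds only "
                f"{total_interactions(src)}"
            )
    rngs = split_rng(seed, 3)
    parts = [
        _sample_counts(src, w, r) if w > 0 else np.zeros(m.n_bins * (m.n_bins + 1) // 2)
        for (name, src), w, r in zip(sources.items(), wants, rngs)
    ]
    counts = symmetric_from_upper(sum(parts), m.n_bins)
    return ContactMatrix(m.chrom, m.resolution, counts, is_raw=True)


def _nested_samples(source: ContactMatrix, sizes: list[int], rng) -> dict[int, np.ndarray]:
    """Without-replacement samples at several sizes, nested: the sample
    at a smaller size is a subsample of the one at the next larger size.
    Returns upper-triangle count vectors keyed by size."""
    out: dict[int, np.ndarray] = {}
    current = np.round(upper_values(source.counts)).astype(np.int64)
    for size in sorted(set(sizes), reverse=True):
        current = rng.multivariate_hypergeometric(current, int(size))
        out[size] = current.astype(float)
    return out


def noise_ladder(
    m: ContactMatrix,
    levels=DEFAULT_NOISE_LEVELS,
    g_share: float = 1.0 / 3.0,
    seed=None,
    stratum_size: int = 100,
) -> list[ContactMatrix]:
    """One mixed matrix per noise level, all with m's total count and
    sharing a single realization of G and R.

    Levels are coupled by common random numbers: each source's samples
    are nested across levels (a lower level's share of a source is a
    subset of a higher level's share), so differences along the ladder
    reflect the noise proportion rather than independent resampling
    jitter.
    """
    levels = list(levels)
    if any(not (0.0 <= f <= 1.0) for f in levels):
        raise ValidationError("noise levels must lie in [0, 1]")
    rngs = split_rng(seed, 5)
    G = genomic_distance_noise(m, stratum_size=stratum_size, seed=rngs[0])
    R = random_ligation_noise(m, seed=rngs[1])
    c = total_interactions(m)
    wants = [
        _largest_remainder(c, np.array([1.0 - f, f * g_share, f * (1.0 - g_share)]))
        for f in levels
    ]
    parts = [
        _nested_samples(src, [int(w[i]) for w in wants], r)
        for i, (src, r) in enumerate(zip((m, G, R), rngs[2:]))
    ]
    out = []
    for w in wants:
        upper = sum(part[int(wi)] for part, wi in zip(parts, w))
        counts = symmetric_from_upper(upper, m.n_bins)
        out.append(ContactMatrix(m.chrom, m.resolution, counts, is_raw=True))
    return out
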