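"""Stratum-adjusted correlation coefficient (SCC) between contact maps.

The score smooths both matrices with a 2D mean filter, stratifies cell
pairs by genomic distance (bin offset), computes a Pearson correlation
per stratum and aggregates them with variance-style weights
w_k = N_k * sd_k(a) * sd_k(b).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import UndefinedScoreError, ValidationError
from .matrix_io import ContactMatrix

__all__ = [
    "SmoothedMatrix",
    "StratumCorrelations",
    "mean_filter",
    "stratify",
    "scc",
    "default_h",
]

#: trained smoothing half-widths by resolution (bp)
DEFAULT_H_BY_RESOLUTION = {10_000: 20, 40_000: 5, 500_000: 1}

#: default maximum stratified genomic distance
DEFAULT_MAX_DISTANCE_BP = 5_000_000


def default_h(resolution: int) -> int:
    """Smoothing half-width for a resolution; nearest known if untrained."""
    if resolution in DEFAULT_H_BY_RESOLUTION:
        return DEFAULT_H_BY_RESOLUTION[resolution]
    known = min(DEFAULT_H_BY_RESOLUTION, key=lambda r: abs(r - resolution))
    return DEFAULT_H_BY_RESOLUTION[known]


@dataclass
class SmoothedMatrix:
    values: np.ndarray
    h: int


@dataclass
class StratumCorrelations:
    distances: np.ndarray  # retained stratum offsets k
    n_pairs: np.ndarray  # N_k
    rho: np.ndarray  # Pearson correlation per stratum
    sd_a: np.ndarray
    sd_b: np.ndarray

    @property
    def weights(self) -> np.ndarray:
        w = self.n_pairs * self.sd_a * self.sd_b
        return w / w.sum()

    @property
    def scc(self) -> float:
        return float(np.dot(self.weights, self.rho))


def mean_filter(m: ContactMatrix | np.ndarray, h: int) -> SmoothedMatrix:
    """Replace each cell with the mean over the (2h+1)^2 window clipped
    to the matrix (no padding counts are invented at the edges)."""
    if h < 0:
        raise ValidationError("h must be >= 0")
    values = m.counts if isinstance(m, ContactMatrix) else np.asarray(m, dtype=float)
    if h == 0:
        return SmoothedMatrix(values.copy(), 0)
    size = 2 * h + 1
    sums = ndimage.uniform_filter(values, size=size, mode="constant", cval=0.0)
    window = ndimage.uniform_filter(np.ones_like(values), size=size, mode="constant", cval=0.0)
    return SmoothedMatrix(sums / window, h)


def stratify(a: SmoothedMatrix, b: SmoothedMatrix, max_distance_bins: int) -> StratumCorrelations:
    """Per-offset Pearson correlations of the two smoothed matrices.

    Stratum k collects cells (i, j) with j - i == k for
    k = 0..max_distance_bins; strata with fewer than two cells or zero
    variance in either vector are dropped.
    """
    va, vb = a.values, b.values
    if va.shape != vb.shape:
        raise ValidationError("matrices must have the same shape")
    if max_distance_bins < 1:
        raise ValidationError("max_distance_bins must be >= 1")
    n = va.shape[0]
    ks, ns, rhos, sda, sdb = [], [], [], [], []
    for k in range(min(max_distance_bins, n - 1) + 1):
        x = np.diagonal(va, k)
        y = np.diagonal(vb, k)
        if x.size < 2:
            continue
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            continue
        rho = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
        ks.append(k)
        ns.append(x.size)
        rhos.append(rho)
        sda.append(sx)
        sdb.append(sy)
    return StratumCorrelations(
        np.array(ks), np.array(ns, dtype=float), np.array(rhos), np.array(sda), np.array(sdb)
    )


def scc(
    a: ContactMatrix,
    b: ContactMatrix,
    h: int | None = None,
    max_distance_bins: int | None = None,
) -> float:
    """Stratum-adjusted correlation coefficient in [-1, 1].

    ``h`` defaults to the trained value for the matrices' resolution;
    ``max_distance_bins`` defaults to 5 Mb expressed in bins.
    """
    if a.counts.shape != b.counts.shape:
        raise ValidationError("matrices must have the same shape")
    if h is None:
        h = default_h(a.resolution)
    if max_distance_bins is None:
        max_distance_bins = max(1, DEFAULT_MAX_DISTANCE_BP // a.resolution)
    sa = mean_filter(a, h)
    sb = mean_filter(b, h)
    strata = stratify(sa, sb, max_distance_bins)
    if strata.rho.size == 0:
        raise UndefinedScoreError("no stratum retained (all too small or zero variance)")
    return float(np.clip(strata.scc, -1.0, 1.0))
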