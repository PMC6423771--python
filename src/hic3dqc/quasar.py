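"""Enrichment-weighted correlation transform, replicate score and the
single-sample quality score.

The transform works within a band of ``window`` bins around the
diagonal. Bins are filtered until every remaining row has a non-zero
off-diagonal entry within the band; the distance background is the mean
count per bin offset over retained pairs; enrichment is count divided by
background; correlations are computed between pairs of rows of the
log-enrichment matrix over shared valid columns inside the band,
excluding the diagonal cells of either row; the interaction weight of a
row pair is sqrt(raw enrichment + 1).

The replicate score correlates two samples' weighted correlation
matrices; the quality score is the difference between the pooled
weighted and unweighted correlation means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .errors import UndefinedScoreError, ValidationError
from .matrix_io import ContactMatrix

__all__ = [
    "QuasarTransform",
    "filter_bins",
    "distance_background",
    "quasar_transform",
    "quasar_rep",
    "quasar_qc",
]

DEFAULT_WINDOW = 100
_VAR_TOL = 1e-12


@dataclass
class QuasarTransform:
    valid_mask: np.ndarray  # retained bins, original coordinates
    background: np.ndarray  # mean count per offset 0..window (NaN if empty)
    log_enrichment: np.ndarray  # NaN where undefined
    corr: np.ndarray  # row-pair correlations, NaN where invalid
    weights: np.ndarray  # sqrt(raw enrichment + 1) per row pair
    window: int

    @property
    def valid_pairs(self) -> np.ndarray:
        """Boolean mask of defined correlation entries (upper triangle)."""
        n = self.corr.shape[0]
        return np.isfinite(self.corr) & (np.arange(n)[None, :] > np.arange(n)[:, None])


def filter_bins(m: ContactMatrix, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Valid-bin mask: iteratively drop bins whose row has no non-zero
    entry at a retained column within ``window`` bins of the diagonal
    (diagonal excluded), until a fixpoint."""
    n = m.n_bins
    counts = m.counts
    valid = np.ones(n, dtype=bool)
    changed = True
    while changed:
        changed = False
        for i in np.flatnonzero(valid):
            lo, hi = max(0, i - window), min(n, i + window + 1)
            seg = counts[i, lo:hi].copy()
            seg[i - lo] = 0.0  # the diagonal cell does not count
            cols_ok = valid[lo:hi]
            if not np.any((seg > 0) & cols_ok):
                valid[i] = False
                changed = True
    if not valid.any():
        raise UndefinedScoreError("all bins filtered out")
    return valid


def distance_background(
    m: ContactMatrix, valid_mask: np.ndarray | None = None, window: int = DEFAULT_WINDOW
) -> np.ndarray:
    """Mean count per bin offset d = 0..window over retained pairs.

    Offsets with no retained pair are NaN (undefined), never silently 0.
    """
    if valid_mask is None:
        valid_mask = filter_bins(m, window)
    n = m.n_bins
    bg = np.full(window + 1, np.nan)
    for d in range(min(window, n - 1) + 1):
        i = np.arange(n - d)
        ok = valid_mask[i] & valid_mask[i + d]
        if ok.any():
            bg[d] = m.counts[i[ok], i[ok] + d].mean()
    return bg


def _pairwise_banded_corr(E: np.ndarray, window: int) -> np.ndarray:
    """Masked Pearson correlation between rows A and B = A + o for every
    offset o = 1..window, over columns within ``window`` of both rows,
    using only jointly finite entries of E. Vectorized per offset."""
    n = E.shape[0]
    corr = np.full((n, n), np.nan)
    for o in range(1, min(window, n - 1) + 1):
        offs = np.arange(o - window, window + 1)
        offs = offs[(offs != 0) & (offs != o)]  # diagonal cells of either row
        i = np.arange(n - o)
        cols = i[:, None] + offs[None, :]
        inb = (cols >= 0) & (cols < n)
        colsc = np.where(inb, cols, 0)
        X = E[i[:, None], colsc]
        Y = E[(i + o)[:, None], colsc]
        mask = inb & np.isfinite(X) & np.isfinite(Y)
        Xm = np.where(mask, X, 0.0)
        Ym = np.where(mask, Y, 0.0)
        cnt = mask.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            sx, sy = Xm.sum(1), Ym.sum(1)
            cov = (Xm * Ym).sum(1) - sx * sy / np.maximum(cnt, 1)
            varx = (Xm * Xm).sum(1) - sx * sx / np.maximum(cnt, 1)
            vary = (Ym * Ym).sum(1) - sy * sy / np.maximum(cnt, 1)
            rho = cov / np.sqrt(varx * vary)
        bad = (cnt < 3) | (varx <= _VAR_TOL) | (vary <= _VAR_TOL)
        rho[bad] = np.nan
        rho = np.clip(rho, -1.0, 1.0)
        corr[i, i + o] = rho
        corr[i + o, i] = rho
    return corr


def quasar_transform(
    m: ContactMatrix, window: int = DEFAULT_WINDOW, valid_mask: np.ndarray | None = None
) -> QuasarTransform:
    """Full transform: filtering, background, log enrichment, banded
    correlation matrix and interaction weights."""
    if valid_mask is None:
        valid_mask = filter_bins(m, window)
    elif not valid_mask.any():
        raise UndefinedScoreError("empty valid mask")
    n = m.n_bins
    bg = distance_background(m, valid_mask, window)

    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    in_band = dist <= window
    bg_full = np.full((n, n), np.nan)
    bg_full[in_band] = bg[dist[in_band]]
    pair_ok = valid_mask[:, None] & valid_mask[None, :] & in_band

    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(pair_ok & (bg_full > 0), m.counts / np.where(bg_full > 0, bg_full, 1.0), 0.0)
        # log enrichment defined only at observed (non-zero) counts
        E = np.where(pair_ok & (m.counts > 0) & (bg_full > 0), np.log(np.maximum(raw, 1e-300)), np.nan)

    corr = _pairwise_banded_corr(E, window)
    # correlations only exist between jointly retained rows
    corr[~valid_mask, :] = np.nan
    corr[:, ~valid_mask] = np.nan
    weights = np.where(np.isfinite(corr), np.sqrt(raw + 1.0), np.nan)
    return QuasarTransform(
        valid_mask=valid_mask,
        background=bg,
        log_enrichment=E,
        corr=corr,
        weights=weights,
        window=window,
    )


def _weighted_corr_matrix(t: QuasarTransform) -> tuple[np.ndarray, np.ndarray]:
    """(weighted correlation values, joint validity mask) on the upper
    triangle; the weighted matrix is corr*weights / sum of valid weights."""
    mask = t.valid_pairs
    if not mask.any():
        raise UndefinedScoreError("no valid correlation entries")
    wsum = t.weights[mask].sum()
    weighted = np.where(mask, t.corr * t.weights / wsum, np.nan)
    return weighted, mask


def quasar_rep(
    a: ContactMatrix | QuasarTransform,
    b: ContactMatrix | QuasarTransform,
    window: int = DEFAULT_WINDOW,
) -> float:
    """Replicate score: Pearson correlation of the two samples' weighted
    correlation matrices over jointly valid row pairs.

    When given raw matrices the two transforms are computed on the
    intersection of the two samples' retained-bin sets.
    """
    if isinstance(a, ContactMatrix) and isinstance(b, ContactMatrix):
        if a.counts.shape != b.counts.shape:
            raise ValidationError("matrices must have the same shape")
        common = filter_bins(a, window) & filter_bins(b, window)
        if not common.any():
            raise UndefinedScoreError("no commonly retained bins")
        ta = quasar_transform(a, window, valid_mask=common)
        tb = quasar_transform(b, window, valid_mask=common)
    else:
        ta, tb = a, b
        if ta.corr.shape != tb.corr.shape:
            raise ValidationError("transforms must have the same shape")
    wa, ma = _weighted_corr_matrix(ta)
    wb, mb = _weighted_corr_matrix(tb)
    joint = ma & mb
    x, y = wa[joint], wb[joint]
    if x.size < 3 or x.std() == 0 or y.std() == 0:
        raise UndefinedScoreError("too few jointly valid entries for a correlation")
    return float(np.corrcoef(x, y)[0, 1])


def quasar_qc(
    matrices: Iterable[ContactMatrix] | ContactMatrix,
    window: int = DEFAULT_WINDOW,
    pooling: str = "pooled",
) -> float:
    """Quality score: weighted correlation mean minus unweighted
    correlation mean, pooled over chromosomes.

    ``pooling='pooled'`` sums numerators/denominators over all
    chromosomes' cells before dividing; ``'per_chromosome'`` averages
    per-chromosome scores instead.
    """
    if isinstance(matrices, ContactMatrix):
        matrices = [matrices]
    num_w = den_w = num_u = den_u = 0.0
    per_chrom = []
    any_defined = False
    for m in matrices:
        try:
            t = m if isinstance(m, QuasarTransform) else quasar_transform(m, window)
            mask = t.valid_pairs
            if not mask.any():
                continue
        except UndefinedScoreError:
            continue
        any_defined = True
        c, w = t.corr[mask], t.weights[mask]
        num_w += float((c * w).sum())
        den_w += float(w.sum())
        num_u += float(c.sum())
        den_u += float(mask.sum())
        per_chrom.append((c * w).sum() / w.sum() - c.mean())
    if not any_defined:
        raise UndefinedScoreError("no chromosome produced a defined transform")
    if pooling == "pooled":
        return num_w / den_w - num_u / den_u
    if pooling == "per_chromosome":
        return float(np.mean(per_chrom))
    raise ValidationError(f"unknown pooling {pooling!r}")
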