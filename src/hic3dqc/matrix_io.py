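"""Data model and text I/O for binned intrachromosomal Hi-C contact matrices.

A :class:`ContactMatrix` stores the full symmetric count matrix densely.
Matrices handled by this package are per-chromosome and small enough
(hundreds to a few thousand bins) that dense storage is the simplest
correct representation; sparse triplet text is the interchange format.

Coordinates are 0-based, half-open bins; triplet rows store bin *start*
coordinates and the upper triangle only (start1 <= start2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ParseError, ValidationError

__all__ = [
    "ContactMatrix",
    "read_contact_matrix",
    "write_contact_matrix",
    "marginals",
    "total_interactions",
]


@dataclass
class ContactMatrix:
    """Symmetric, non-negative binned contact matrix for one chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome label.
    resolution : int
        Bin width in base pairs.
    counts : ndarray of shape (n_bins, n_bins)
        Full symmetric matrix of interaction counts.
    is_raw : bool
        True when entries are raw (integer) counts; False for
        transformed real-valued matrices.
    """

    chrom: str
    resolution: int
    counts: np.ndarray
    is_raw: bool = True

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValidationError("counts must be a square 2D matrix")
        if not np.all(np.isfinite(self.counts)):
            raise ValidationError("counts must be finite")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        if not np.allclose(self.counts, self.counts.T):
            raise ValidationError("counts must be symmetric")
        if self.is_raw and not np.allclose(self.counts, np.round(self.counts)):
            raise ValidationError("raw counts must be integers")
        if self.resolution <= 0:
            raise ValidationError("resolution must be positive")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(self.chrom, self.resolution, self.counts.copy(), self.is_raw)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ContactMatrix):
            return NotImplemented
        return (
            self.chrom == other.chrom
            and self.resolution == other.resolution
            and self.counts.shape == other.counts.shape
            and np.array_equal(self.counts, other.counts)
        )


def n_bins_for_length(chrom_length: int, resolution: int) -> int:
    return int(math.ceil(chrom_length / resolution))


def read_contact_matrix(
    path,
    format: str = "triplet",
    resolution: int | None = None,
    chrom_length: int | None = None,
    chrom: str | None = None,
) -> ContactMatrix:
    """Read a contact matrix from triplet or dense TSV text.

    Triplet format: TAB-separated ``chrom  start1  start2  count`` with no
    header; lines starting with '#' are comments. Entries given once per
    unordered pair are mirrored; duplicate pairs are summed.
    """
    path = Path(path)
    if format == "triplet":
        return _read_triplet(path, resolution, chrom_length, chrom)
    if format == "dense":
        if resolution is None:
            raise ValidationError("dense format requires a resolution")
        counts = np.loadtxt(path, delimiter="\t", ndmin=2)
        is_raw = bool(np.allclose(counts, np.round(counts)))
        return ContactMatrix(chrom or "chr?", resolution, counts, is_raw=is_raw)
    raise ValidationError(f"unknown format: {format!r}")


def _read_triplet(path: Path, resolution, chrom_length, chrom) -> ContactMatrix:
    if resolution is None:
        raise ValidationError("triplet format requires a resolution")
    rows: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 tab-separated columns, got {len(parts)}")
            c, s1, s2, cnt = parts
            try:
                s1i, s2i = int(s1), int(s2)
                cntf = float(cnt)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field ({exc})")
            if cntf < 0:
                raise ValidationError(f"{path}:{lineno}: negative count {cntf}")
            if s1i % resolution or s2i % resolution:
                raise ValidationError(
                    f"{path}:{lineno}: start not a multiple of resolution {resolution}"
                )
            rows.append((c, s1i, s2i, cntf))

    if chrom is None:
        chrom = rows[0][0] if rows else "chr?"
    max_start = max((max(r[1], r[2]) for r in rows), default=-resolution)
    n = max_start // resolution + 1
    if chrom_length is not None:
        n = max(n, n_bins_for_length(chrom_length, resolution))
    n = max(n, 0)
    counts = np.zeros((n, n))
    for _, s1, s2, cnt in rows:
        i, j = s1 // resolution, s2 // resolution
        counts[i, j] += cnt
        if i != j:
            counts[j, i] += cnt
    is_raw = bool(np.allclose(counts, np.round(counts)))
    return ContactMatrix(chrom, resolution, counts, is_raw=is_raw)


def write_contact_matrix(m: ContactMatrix, path, format: str = "triplet") -> None:
    """Write ``m`` so that reading it back reproduces it exactly.

    Triplet output emits one row per non-zero unordered pair, upper
    triangle convention (start1 <= start2).
    """
    path = Path(path)
    if format == "triplet":
        res = m.resolution
        with open(path, "w") as fh:
            iu = np.triu_indices(m.n_bins)
            vals = m.counts[iu]
            for i, j, v in zip(iu[0], iu[1], vals):
                if v != 0:
                    v_str = str(int(v)) if float(v).is_integer() else repr(float(v))
                    fh.write(f"{m.chrom}\t{i * res}\t{j * res}\t{v_str}\n")
    elif format == "dense":
        fmt = "%d" if m.is_raw else "%.17g"
        np.savetxt(path, m.counts, delimiter="\t", fmt=fmt)
    else:
        raise ValidationError(f"unknown format: {format!r}")


def marginals(m: ContactMatrix) -> np.ndarray:
    """Per-bin totals: row sums of the full symmetric matrix."""
    return m.counts.sum(axis=1)


def total_interactions(m: ContactMatrix) -> float:
    """Total interaction count: sum over unordered bin pairs (upper
    triangle including the diagonal)."""
    total = np.triu(m.counts).sum()
    return int(round(total)) if m.is_raw else float(total)
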