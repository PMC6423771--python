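"""Uniform downsampling of contact matrices and pseudo-replicate construction.

Downsampling treats each unit count as one individual interaction and
draws a subset uniformly *without* replacement (multivariate
hypergeometric over bin pairs), modelling retention of a subset of real
ligation events. Pseudo-replicates pool two biological replicates and
draw two independent downsamples of the pooled matrix, each holding the
average of the two original totals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import rng_from, split_rng, symmetric_from_upper, upper_values
from .errors import ValidationError
from .matrix_io import ContactMatrix, total_interactions

__all__ = ["ReplicatePair", "downsample", "pseudo_replicates", "coverage_ladder"]

DEFAULT_COVERAGE_TARGETS = (
    30_000_000,
    25_000_000,
    20_000_000,
    15_000_000,
    10_000_000,
    5_000_000,
    1_000_000,
)


@dataclass
class ReplicatePair:
    """A labeled pair of contact matrices to be scored."""

    a: ContactMatrix
    b: ContactMatrix
    label: str  # {"biological", "pseudo", "non_replicate"}
    cell_type_a: str = ""
    cell_type_b: str = ""

    def __post_init__(self) -> None:
        if self.label not in {"biological", "pseudo", "non_replicate"}:
            raise ValidationError(f"unknown pair label {self.label!r}")
        if (self.label == "non_replicate") != (self.cell_type_a != self.cell_type_b):
            raise ValidationError("label must be non_replicate iff cell types differ")

    @property
    def coverage(self) -> float:
        return (total_interactions(self.a) + total_interactions(self.b)) / 2


def downsample(m: ContactMatrix, n: int, seed) -> ContactMatrix:
    """Draw exactly ``n`` interactions uniformly without replacement."""
    total = total_interactions(m)
    if not m.is_raw:
        raise ValidationError("can only downsample raw count matrices")
    if n < 0 or n > total:
        raise ValidationError(f"cannot downsample to {n} from total {total}")
    rng = rng_from(seed)
    colors = np.round(upper_values(m.counts)).astype(np.int64)
    kept = rng.multivariate_hypergeometric(colors, int(n))
    out = symmetric_from_upper(kept.astype(float), m.n_bins)
    return ContactMatrix(m.chrom, m.resolution, out, is_raw=True)


def pseudo_replicates(a: ContactMatrix, b: ContactMatrix, seed) -> tuple[ContactMatrix, ContactMatrix]:
    """Pool two replicates and return two independent downsamples of the
    pooled matrix, each with the average of the two original totals."""
    if a.counts.shape != b.counts.shape:
        raise ValidationError("replicates must have the same shape")
    pooled = ContactMatrix(a.chrom, a.resolution, a.counts + b.counts, is_raw=True)
    target = int(round((total_interactions(a) + total_interactions(b)) / 2))
    r1, r2 = split_rng(seed, 2)
    return downsample(pooled, target, r1), downsample(pooled, target, r2)


def coverage_ladder(m: ContactMatrix, targets=DEFAULT_COVERAGE_TARGETS, seed=None) -> list[ContactMatrix]:
    """Independent downsamples of ``m`` at each target total."""
    targets = list(targets)
    if targets and max(targets) > total_interactions(m):
        raise ValidationError("coverage target exceeds available interactions")
    rngs = split_rng(seed, len(targets))
    return [downsample(m, t, r) for t, r in zip(targets, rngs)]
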