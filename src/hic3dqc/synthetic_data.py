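"""Synthetic ground-truth contact intensities and sampled replicates.

The noise-free intensity is a product model

    lambda(i, j) = bias_i * bias_j * (|i - j| + 1)**decay_exponent
                   * tad_factor(i, j) * compartment_factor(i, j)

capturing the two structures the reproducibility scores respond to:
the monotone decay of contact frequency with genomic distance, and
block (domain / compartment) enrichment. Replicates are multinomial
samples from lambda; biological-replicate variability adds a small
per-replicate lognormal bias jitter so that pseudo-replicates (pure
resampling) are strictly cleaner than biological replicates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from ._util import rng_from, split_rng, symmetric_from_upper, upper_values
from .errors import ValidationError
from .matrix_io import ContactMatrix
from .resampling import ReplicatePair, pseudo_replicates

__all__ = [
    "SyntheticGroundTruth",
    "BenchmarkSet",
    "simulate_cell_type",
    "sample_replicate",
    "make_benchmark",
]


@dataclass
class SyntheticGroundTruth:
    n_bins: int
    decay_exponent: float
    tad_boundaries: np.ndarray  # strictly increasing interior boundaries
    tad_enrichment: float
    compartment_labels: np.ndarray  # per-bin 0/1 (A/B)
    compartment_enrichment: float
    bias: np.ndarray  # per-bin positive multiplier
    resolution: int = 40_000
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        b = np.asarray(self.tad_boundaries, dtype=int)
        if np.any(np.diff(b) <= 0) or (b.size and (b[0] < 0 or b[-1] > self.n_bins)):
            raise ValidationError("tad_boundaries must be strictly increasing within [0, n_bins]")
        if np.any(self.bias <= 0):
            raise ValidationError("bias must be positive")
        self.tad_boundaries = b

    @property
    def intensity(self) -> np.ndarray:
        """Symmetric positive intensity matrix lambda."""
        n = self.n_bins
        idx = np.arange(n)
        dist = np.abs(idx[:, None] - idx[None, :])
        lam = (dist + 1.0) ** self.decay_exponent
        # TAD factor: enrichment for pairs inside the same domain
        edges = np.concatenate(([0], self.tad_boundaries, [n]))
        domain = np.searchsorted(edges, idx, side="right")
        same_tad = domain[:, None] == domain[None, :]
        if self.tad_enrichment != 1.0 and len(edges) > 2:
            lam = lam * np.where(same_tad, self.tad_enrichment, 1.0)
        # compartment factor: same-label pairs outside a TAD
        lab = np.asarray(self.compartment_labels)
        same_comp = lab[:, None] == lab[None, :]
        if self.compartment_enrichment != 1.0:
            lam = lam * np.where(same_comp & ~same_tad, self.compartment_enrichment, 1.0)
        lam = lam * np.outer(self.bias, self.bias)
        return lam


@dataclass
class BenchmarkSet:
    """Labeled replicate pairs plus the ladders used to build them."""

    pairs: list[ReplicatePair]
    ground_truths: dict[str, SyntheticGroundTruth] = field(default_factory=dict)
    noise_levels: tuple = ()
    coverage_targets: tuple = ()
    seed: int | None = None

    def by_label(self, label: str) -> list[ReplicatePair]:
        return [p for p in self.pairs if p.label == label]


def simulate_cell_type(
    n_bins: int,
    decay_exponent: float = -1.0,
    n_tads: int = 10,
    tad_enrichment: float = 3.0,
    compartment_enrichment: float = 1.5,
    bias_spread: float = 0.2,
    seed=None,
    resolution: int = 40_000,
    chrom: str = "chrS",
) -> SyntheticGroundTruth:
    """Draw a random ground truth: TAD boundaries, compartments, biases."""
    if n_bins < 10:
        raise ValidationError("n_bins must be >= 10")
    if decay_exponent >= 0:
        raise ValidationError("decay_exponent must be negative")
    if n_tads < 0 or bias_spread < 0:
        raise ValidationError("n_tads and bias_spread must be non-negative")
    rng = rng_from(seed)
    if n_tads > 0:
        boundaries = np.sort(rng.choice(np.arange(1, n_bins), size=min(n_tads - 1, n_bins - 2) if n_tads > 1 else 0, replace=False))
    else:
        boundaries = np.array([], dtype=int)
    # compartments alternate in random-length stretches
    labels = np.zeros(n_bins, dtype=int)
    pos, lab = 0, int(rng.integers(2))
    while pos < n_bins:
        run = int(rng.integers(n_bins // 10, n_bins // 3 + 1))
        labels[pos : pos + run] = lab
        lab = 1 - lab
        pos += run
    bias = rng.lognormal(mean=0.0, sigma=bias_spread, size=n_bins) if bias_spread > 0 else np.ones(n_bins)
    return SyntheticGroundTruth(
        n_bins=n_bins,
        decay_exponent=decay_exponent,
        tad_boundaries=boundaries,
        tad_enrichment=tad_enrichment if n_tads > 0 else 1.0,
        compartment_labels=labels,
        compartment_enrichment=compartment_enrichment,
        bias=bias,
        resolution=resolution,
        chrom=chrom,
    )


def sample_replicate(
    gt: SyntheticGroundTruth,
    n_interactions: int,
    seed=None,
    bias_jitter: float = 0.0,
) -> ContactMatrix:
    """Multinomial sample of ``n_interactions`` unordered bin pairs with
    probabilities proportional to lambda.

    ``bias_jitter`` applies a per-replicate lognormal per-bin multiplier
    (sigma = bias_jitter) to lambda before sampling, emulating
    replicate-to-replicate bias drift.
    """
    if n_interactions < 0:
        raise ValidationError("n_interactions must be >= 0")
    rng = rng_from(seed)
    lam = gt.intensity
    if bias_jitter > 0:
        j = rng.lognormal(0.0, bias_jitter, size=gt.n_bins)
        lam = lam * np.outer(j, j)
    probs = upper_values(lam)
    probs = probs / probs.sum()
    draws = rng.multinomial(int(n_interactions), probs)
    counts = symmetric_from_upper(draws.astype(float), gt.n_bins)
    return ContactMatrix(gt.chrom, gt.resolution, counts, is_raw=True)


def make_benchmark(
    n_cell_types: int = 4,
    reps_per_type: int = 2,
    n_interactions: int = 5_000_000,
    seed=None,
    n_bins: int = 500,
    bias_jitter: float = 0.05,
    include_pseudo: bool = True,
    **gt_kwargs,
) -> BenchmarkSet:
    """Build a labeled benchmark: per-type biological replicate pairs,
    all cross-type non-replicate pairs, and pseudo-replicate pairs
    derived from each type's first two replicates."""
    if n_cell_types < 2:
        raise ValidationError("need at least 2 cell types")
    if reps_per_type < 2:
        raise ValidationError("need at least 2 replicates per type")
    master = rng_from(seed)
    gt_rngs = split_rng(master, n_cell_types * (reps_per_type + 2))
    it = iter(gt_rngs)

    ground_truths: dict[str, SyntheticGroundTruth] = {}
    reps: dict[str, list[ContactMatrix]] = {}
    pairs: list[ReplicatePair] = []
    for t in range(n_cell_types):
        name = f"type{t}"
        gt = simulate_cell_type(n_bins, seed=next(it), chrom=name, **gt_kwargs)
        ground_truths[name] = gt
        reps[name] = [
            sample_replicate(gt, n_interactions, seed=next(it), bias_jitter=bias_jitter)
            for _ in range(reps_per_type)
        ]
        for i, j in itertools.combinations(range(reps_per_type), 2):
            pairs.append(ReplicatePair(reps[name][i], reps[name][j], "biological", name, name))
        if include_pseudo:
            p1, p2 = pseudo_replicates(reps[name][0], reps[name][1], next(it))
            pairs.append(ReplicatePair(p1, p2, "pseudo", name, name))

    for ta, tb in itertools.combinations(sorted(reps), 2):
        for a in reps[ta]:
            for b in reps[tb]:
                pairs.append(ReplicatePair(a, b, "non_replicate", ta, tb))

    return BenchmarkSet(pairs=pairs, ground_truths=ground_truths, seed=seed)
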