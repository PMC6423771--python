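"""Internal helpers: RNG plumbing and upper-triangle (un)flattening."""

from __future__ import annotations

import numpy as np


def rng_from(seed) -> np.random.Generator:
    """Build a Generator from an int seed, SeedSequence or Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def split_rng(seed, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent child generators from one seed."""
    if isinstance(seed, np.random.Generator):
        ss = seed.bit_generator.seed_seq
    else:
        ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def upper_values(counts: np.ndarray) -> np.ndarray:
    """Flatten the upper triangle (incl. diagonal) into a 1-D vector."""
    iu = np.triu_indices(counts.shape[0])
    return counts[iu]


def symmetric_from_upper(values: np.ndarray, n: int) -> np.ndarray:
    """Rebuild a full symmetric matrix from upper-triangle values."""
    out = np.zeros((n, n))
    iu = np.triu_indices(n)
    out[iu] = values
    out = out + out.T - np.diag(np.diag(out))
    return out
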