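"""Score aggregation, empirical thresholds and ranking experiments.

This module dispatches the four replicate scores behind one name-based
interface, averages per-chromosome scores into a genome-level score,
derives empirical decision thresholds from labeled score distributions
and runs the noise-response and replicate-type ranking experiments on a
labeled benchmark set.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np
from scipy import stats

from ._util import split_rng
from .errors import UndefinedScoreError, ValidationError
from .genomedisco import disco_score
from .hicrep import scc
from .hicspector import spector_score
from .matrix_io import ContactMatrix, total_interactions
from .noise_sim import DEFAULT_NOISE_LEVELS, noise_ladder
from .quasar import quasar_qc, quasar_rep
from .resampling import ReplicatePair, downsample
from .synthetic_data import BenchmarkSet

__all__ = [
    "ScoreReport",
    "METHODS",
    "score_pair",
    "genome_score",
    "empirical_threshold",
    "ranking_evaluation",
    "noise_response_curve",
]

log = logging.getLogger("hic3dqc")


def _scc_method(a, b, seed=None, **kw):
    return scc(a, b, **kw)


def _disco_method(a, b, seed=None, **kw):
    return disco_score(a, b, seed=seed, **kw)


def _spector_method(a, b, seed=None, **kw):
    return spector_score(a, b, **kw)


def _quasar_method(a, b, seed=None, **kw):
    return quasar_rep(a, b, **kw)


METHODS: Mapping[str, Callable] = {
    "hicrep": _scc_method,
    "genomedisco": _disco_method,
    "hicspector": _spector_method,
    "quasar-rep": _quasar_method,
}


def score_pair(method: str, a: ContactMatrix, b: ContactMatrix, seed=None, **kwargs) -> float:
    if method not in METHODS:
        raise ValidationError(f"unknown method {method!r}; choose from {sorted(METHODS)}")
    return METHODS[method](a, b, seed=seed, **kwargs)


@dataclass
class ScoreReport:
    """Per-chromosome scores and their genome-level mean for one pair."""

    method: str
    per_chromosome: dict[str, float | None]
    pair: ReplicatePair | None = None

    @property
    def genome_score(self) -> float:
        return genome_score(self.per_chromosome)


def genome_score(per_chromosome: Mapping[str, float | None]) -> float:
    """Arithmetic mean of the defined per-chromosome scores; undefined
    chromosomes are dropped with a warning rather than counted as 0."""
    defined = {k: v for k, v in per_chromosome.items() if v is not None and np.isfinite(v)}
    dropped = set(per_chromosome) - set(defined)
    if dropped:
        log.warning("dropping undefined chromosome scores: %s", sorted(dropped))
    if not defined:
        raise UndefinedScoreError("no chromosome has a defined score")
    return float(np.mean(list(defined.values())))


def empirical_threshold(nonrep_scores: Iterable[float], biorep_scores: Iterable[float]) -> tuple[float, float]:
    """Midpoint of the best non-replicate score and the worst biological
    replicate score; also returns the (possibly negative) margin
    min(biorep) - max(nonrep)."""
    nonrep = list(nonrep_scores)
    biorep = list(biorep_scores)
    if not nonrep or not biorep:
        raise ValidationError("both score lists must be non-empty")
    hi_non, lo_bio = max(nonrep), min(biorep)
    margin = lo_bio - hi_non
    if margin < 0:
        log.warning("score distributions overlap (margin %.4f)", margin)
    return (hi_non + lo_bio) / 2.0, margin


@dataclass
class RankingReport:
    method: str
    scores: dict[str, list[float]]  # label -> scores
    ordering_accuracy: float  # fraction of (bio, nonrep) pairs correctly ordered
    per_type_ordering_ok: dict[str, bool]  # pseudo >= bio >= nonrep per cell type
    threshold: float
    margin: float
    ks_statistic: float
    ks_pvalue: float


def ranking_evaluation(bench: BenchmarkSet, method: str, seed=None, **kwargs) -> RankingReport:
    """Score every pair in the benchmark and evaluate the expected
    ordering pseudo >= biological >= non-replicate."""
    labels = {p.label for p in bench.pairs}
    if not {"biological", "non_replicate"} <= labels:
        raise ValidationError("benchmark must contain biological and non-replicate pairs")
    rngs = split_rng(seed, len(bench.pairs))
    scores: dict[str, list[float]] = {"biological": [], "pseudo": [], "non_replicate": []}
    per_pair: list[tuple[ReplicatePair, float]] = []
    for p, r in zip(bench.pairs, rngs):
        s = score_pair(method, p.a, p.b, seed=r, **kwargs)
        scores[p.label].append(s)
        per_pair.append((p, s))

    bio, non = scores["biological"], scores["non_replicate"]
    n_ordered = sum(1 for b in bio for x in non if b > x)
    accuracy = n_ordered / (len(bio) * len(non))

    per_type: dict[str, bool] = {}
    types = {p.cell_type_a for p, _ in per_pair if p.label == "biological"}
    worst_non = max(non)
    for t in sorted(types):
        t_bio = [s for p, s in per_pair if p.label == "biological" and p.cell_type_a == t]
        t_pse = [s for p, s in per_pair if p.label == "pseudo" and p.cell_type_a == t]
        ok = min(t_bio) > worst_non
        if t_pse:
            ok = ok and (min(t_pse) >= max(t_bio) or np.isclose(min(t_pse), max(t_bio)))
        per_type[t] = bool(ok)

    threshold, margin = empirical_threshold(non, bio)
    ks = stats.ks_2samp(bio, non, alternative="less")  # bio expected larger
    return RankingReport(
        method=method,
        scores=scores,
        ordering_accuracy=accuracy,
        per_type_ordering_ok=per_type,
        threshold=threshold,
        margin=margin,
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
    )


def noise_response_curve(
    m: ContactMatrix,
    method: str,
    levels=(0.0,) + DEFAULT_NOISE_LEVELS,
    g_share: float = 1.0 / 3.0,
    seed=None,
    **kwargs,
) -> list[tuple[float, float]]:
    """Score a clean resample of ``m`` against noise-ladder members.

    The reference is a uniform resample of ``m`` at its own total (a 0%
    noise pseudo-replicate), compared against one mixed matrix per noise
    level; returns (level, score) pairs.
    """
    levels = list(levels)
    r_ref, r_lad, r_score = split_rng(seed, 3)
    n = total_interactions(m)
    reference = downsample(m, int(n), r_ref)
    ladder = noise_ladder(m, levels=levels, g_share=g_share, seed=r_lad)
    out = []
    for lvl, noisy, r in zip(levels, ladder, split_rng(r_score, len(levels))):
        out.append((lvl, score_pair(method, reference, noisy, seed=r, **kwargs)))
    return out
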