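import numpy as np
import pytest

from hic3dqc.errors import UndefinedScoreError
from hic3dqc.matrix_io import ContactMatrix
from hic3dqc.quasar import (
    distance_background,
    filter_bins,
    quasar_qc,
    quasar_rep,
    quasar_transform,
)

from conftest import make_matrix, random_matrix


def brute_force_banded_corr(E, window):
    """Two-pass Pearson oracle over all row pairs within the band."""
    n = E.shape[0]
    corr = np.full((n, n), np.nan)
    for A in range(n):
        for B in range(A + 1, min(A + window, n - 1) + 1):
            xs, ys = [], []
            for j in range(n):
                if abs(j - A) > window or abs(j - B) > window or j in (A, B):
                    continue
                if np.isfinite(E[A, j]) and np.isfinite(E[B, j]):
                    xs.append(E[A, j])
                    ys.append(E[B, j])
            if len(xs) >= 3 and np.std(xs) > 1e-9 and np.std(ys) > 1e-9:
                corr[A, B] = corr[B, A] = np.corrcoef(xs, ys)[0, 1]
    return corr


def dense_random_matrix(n, rng, lo=1, hi=12):
    upper = rng.integers(lo, hi, size=(n, n))
    counts = np.triu(upper, 1)
    counts = counts + counts.T
    return make_matrix(counts)


class TestFilterBins:
    def test_band_positive_keeps_all(self, rng):
        m = dense_random_matrix(10, rng)
        assert filter_bins(m, window=100).all()

    def test_isolated_bin_removed(self, rng):
        m = dense_random_matrix(8, rng)
        counts = m.counts.copy()
        counts[3, :] = counts[:, 3] = 0
        m = make_matrix(counts)
        mask = filter_bins(m, window=100)
        assert not mask[3]
        assert mask.sum() == 7

    def test_diagonal_does_not_count(self):
        counts = np.diag([5.0, 5.0, 5.0])
        with pytest.raises(UndefinedScoreError):
            filter_bins(make_matrix(counts), window=100)

    def test_idempotent(self, rng):
        m = dense_random_matrix(10, rng)
        counts = m.counts.copy()
        counts[4, :] = counts[:, 4] = 0
        m = make_matrix(counts)
        mask1 = filter_bins(m, window=100)
        sub = m.counts.copy()
        sub[~mask1, :] = 0
        sub[:, ~mask1] = 0
        mask2 = filter_bins(make_matrix(sub), window=100)
        np.testing.assert_array_equal(mask1, mask2)


class TestDistanceBackground:
    def test_constant_matrix(self):
        m = make_matrix(np.full((6, 6), 4))
        bg = distance_background(m, np.ones(6, dtype=bool), window=100)
        np.testing.assert_allclose(bg[:6], 4.0)

    def test_empty_distance_is_nan(self):
        m = make_matrix(np.full((4, 4), 2))
        bg = distance_background(m, np.ones(4, dtype=bool), window=100)
        assert np.isnan(bg[10])  # no pair at offset 10 in a 4-bin matrix

    def test_three_bin_example(self):
        m = make_matrix([[0, 4, 0], [4, 0, 2], [0, 2, 0]])
        bg = distance_background(m, np.ones(3, dtype=bool), window=100)
        assert bg[1] == pytest.approx(3.0)  # mean of {4, 2}


class TestQuasarTransform:
    def test_flat_matrix_has_no_valid_correlations(self):
        m = make_matrix(np.full((8, 8), 5))
        t = quasar_transform(m, window=100)
        assert not np.isfinite(t.corr).any()
        with pytest.raises(UndefinedScoreError):
            quasar_rep(t, t)

    def test_corr_matches_brute_force(self, rng):
        for w in (3, 100):
            m = dense_random_matrix(20, rng)
            t = quasar_transform(m, window=w)
            expected = brute_force_banded_corr(t.log_enrichment, w)
            both = np.isfinite(t.corr) & np.isfinite(expected)
            np.testing.assert_allclose(t.corr[both], expected[both], atol=1e-10)
            np.testing.assert_array_equal(np.isfinite(t.corr), np.isfinite(expected))

    def test_band_respected(self, rng):
        m = dense_random_matrix(12, rng)
        t = quasar_transform(m, window=2)
        idx = np.arange(12)
        far = np.abs(idx[:, None] - idx[None, :]) > 2
        assert not np.isfinite(t.corr[far]).any()

    def test_weight_formula(self, rng):
        m = dense_random_matrix(15, rng)
        t = quasar_transform(m, window=100)
        idx = np.arange(15)
        dist = np.abs(idx[:, None] - idx[None, :])
        finite = np.isfinite(t.weights)
        raw = m.counts[finite] / t.background[dist[finite]]
        np.testing.assert_allclose(t.weights[finite], np.sqrt(raw + 1.0), atol=1e-12)

    def test_enrichment_three_gives_weight_two(self):
        counts = np.zeros((5, 5))
        d1 = [9, 1, 1, 1]
        d2 = [5, 2, 2]
        d3 = [4, 2]
        for off, vals in ((1, d1), (2, d2), (3, d3), (4, [3])):
            for i, v in enumerate(vals):
                counts[i, i + off] = counts[i + off, i] = v
        t = quasar_transform(make_matrix(counts), window=100)
        assert t.background[1] == pytest.approx(3.0)
        assert t.weights[0, 1] == pytest.approx(2.0)  # sqrt(9/3 + 1)

    def test_identical_rows_correlate_perfectly(self, rng):
        # structured matrix: contacts depend smoothly on (i, j), adjacent
        # rows nearly identical; self-transform corr diagonal band is high
        m = dense_random_matrix(15, rng)
        t = quasar_transform(m, window=100)
        finite = np.isfinite(t.corr)
        assert np.all(np.abs(t.corr[finite]) <= 1.0 + 1e-12)


class TestQuasarRep:
    def test_self_is_exactly_one(self, medium_replicate):
        assert quasar_rep(medium_replicate, medium_replicate) == pytest.approx(1.0, abs=1e-12)

    def test_symmetric(self, rng):
        a = dense_random_matrix(20, rng)
        b = dense_random_matrix(20, rng)
        assert quasar_rep(a, b) == pytest.approx(quasar_rep(b, a), abs=1e-12)

    def test_uses_common_bin_set(self, rng):
        a = dense_random_matrix(12, rng)
        counts = a.counts.copy()
        counts[5, :] = counts[:, 5] = 0
        b = make_matrix(counts)
        s = quasar_rep(a, b)
        assert -1.0 <= s <= 1.0


class TestQuasarQC:
    def test_random_ligation_matrix_scores_near_zero(self):
        # no distance-conditional structure beyond background: QC ~ 0
        n, total = 200, 1_000_000
        iu = np.triu_indices(n)
        p = np.where(iu[0] == iu[1], 1.0, 2.0)
        p = p / p.sum()
        qcs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            draws = rng.multinomial(total, p)
            counts = np.zeros((n, n))
            counts[iu] = draws
            counts = counts + counts.T - np.diag(np.diag(counts))
            qcs.append(quasar_qc(ContactMatrix("c", 40_000, counts)))
        assert abs(np.mean(qcs)) < 0.01

    def test_structured_matrix_scores_positive(self, medium_replicate):
        assert quasar_qc(medium_replicate) > 0.0

    def test_flat_matrices_undefined(self):
        m = make_matrix(np.full((8, 8), 5))
        with pytest.raises(UndefinedScoreError):
            quasar_qc([m])

    def test_pooled_vs_per_chromosome_agree_on_single_chrom(self, medium_replicate):
        pooled = quasar_qc(medium_replicate, pooling="pooled")
        per = quasar_qc(medium_replicate, pooling="per_chromosome")
        assert pooled == pytest.approx(per, abs=1e-12)

    def test_multi_chromosome_pooling(self, rng):
        a = dense_random_matrix(25, rng)
        b = dense_random_matrix(25, rng)
        q = quasar_qc([a, b])
        assert np.isfinite(q)
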