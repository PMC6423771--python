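import numpy as np
import pytest

from hic3dqc.errors import ValidationError
from hic3dqc.matrix_io import marginals, total_interactions
from hic3dqc.noise_sim import (
    DEFAULT_NOISE_LEVELS,
    NoiseMix,
    genomic_distance_noise,
    mix_matrices,
    noise_ladder,
    random_ligation_noise,
)

from conftest import make_matrix, random_matrix


def offset_sums(counts):
    n = counts.shape[0]
    return np.array([np.diagonal(counts, d).sum() for d in range(n)])


class TestGenomicDistanceNoise:
    def test_constant_per_offset_is_fixed_point(self):
        n = 12
        idx = np.arange(n)
        counts = 20 - np.abs(idx[:, None] - idx[None, :])
        m = make_matrix(counts)
        g = genomic_distance_noise(m, seed=0)
        np.testing.assert_array_equal(g.counts, m.counts)

    def test_per_offset_sums_preserved(self, rng):
        m = random_matrix(30, rng)
        g = genomic_distance_noise(m, seed=1)
        np.testing.assert_array_equal(offset_sums(g.counts), offset_sums(m.counts))

    def test_per_offset_multisets_preserved(self, rng):
        m = random_matrix(20, rng)
        g = genomic_distance_noise(m, seed=2)
        for d in range(20):
            assert sorted(np.diagonal(g.counts, d)) == sorted(np.diagonal(m.counts, d))

    def test_singleton_strata_forbid_movement(self, rng):
        m = random_matrix(15, rng)
        g = genomic_distance_noise(m, stratum_size=1, seed=3)
        np.testing.assert_array_equal(g.counts, m.counts)

    def test_deterministic(self, rng):
        m = random_matrix(25, rng)
        g1 = genomic_distance_noise(m, seed=11)
        g2 = genomic_distance_noise(m, seed=11)
        np.testing.assert_array_equal(g1.counts, g2.counts)

    def test_destroys_block_structure(self):
        # a strong block matrix loses its within-block contrast
        n = 40
        counts = np.ones((n, n))
        counts[:20, :20] += 30
        counts[20:, 20:] += 30
        m = make_matrix(counts)
        g = genomic_distance_noise(m, seed=4)
        within = g.counts[:20, :20].mean() + g.counts[20:, 20:].mean()
        between = 2 * g.counts[:20, 20:].mean()
        orig_contrast = (m.counts[:20, :20].mean() + m.counts[20:, 20:].mean()) / (
            2 * m.counts[:20, 20:].mean()
        )
        assert within / between < orig_contrast


class TestRandomLigationNoise:
    def test_total_conserved(self, rng):
        m = random_matrix(15, rng)
        r = random_ligation_noise(m, seed=5)
        assert total_interactions(r) == total_interactions(m)

    def test_zero_marginal_row_stays_zero(self):
        counts = np.zeros((5, 5))
        counts[0, 1] = counts[1, 0] = 40
        counts[3, 4] = counts[4, 3] = 60
        m = make_matrix(counts)
        r = random_ligation_noise(m, seed=6)
        assert not r.counts[2, :].any()

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            random_ligation_noise(make_matrix(np.zeros((4, 4))), seed=0)

    def test_uniform_marginals_give_uniform_pairs(self):
        # a matrix with uniform marginals: R pair frequencies follow the
        # product law, uniform over ordered pairs, within 3 SE
        n = 20
        counts = np.full((n, n), 250)
        m = make_matrix(counts)
        r = random_ligation_noise(m, seed=7)
        N = total_interactions(m)
        # ordered-pair probability 1/n^2; unordered off-diag cell collects 2/n^2
        iu = np.triu_indices(n)
        p = np.where(iu[0] == iu[1], 1.0, 2.0) / n**2
        obs = r.counts[iu]
        se = np.sqrt(N * p * (1 - p))
        assert (np.abs(obs - N * p) <= 3 * se).mean() > 0.98

    def test_deterministic(self, rng):
        m = random_matrix(10, rng)
        r1 = random_ligation_noise(m, seed=8)
        r2 = random_ligation_noise(m, seed=8)
        np.testing.assert_array_equal(r1.counts, r2.counts)


def disjoint_sources(n=8, total=300):
    """m, G, R with disjoint supports so the mixture origin is identifiable."""
    a = np.zeros((n, n)); a[0, 1] = a[1, 0] = total
    b = np.zeros((n, n)); b[2, 3] = b[3, 2] = total
    c = np.zeros((n, n)); c[4, 5] = c[5, 4] = total
    return make_matrix(a), make_matrix(b), make_matrix(c)


class TestMixMatrices:
    def test_zero_noise_is_resample_of_m(self, rng):
        m = random_matrix(10, rng)
        N = total_interactions(m)
        g = genomic_distance_noise(m, seed=1)
        r = random_ligation_noise(m, seed=2)
        out = mix_matrices(m, g, r, NoiseMix(N, 0.0), seed=3)
        # sampling all N interactions without replacement returns m itself
        np.testing.assert_array_equal(out.counts, m.counts)

    def test_exact_source_apportionment(self):
        m, g, r = disjoint_sources(total=300_000)
        out = mix_matrices(m, g, r, NoiseMix(300_000, 1.0, g_share=1 / 3), seed=0)
        assert out.counts[2, 3] == 100_000  # exactly one third from G
        assert out.counts[4, 5] == 200_000
        assert out.counts[0, 1] == 0

    def test_total_exact_with_rounding(self):
        m, g, r = disjoint_sources(total=1000)
        out = mix_matrices(m, g, r, NoiseMix(1000, 0.15, g_share=1 / 3), seed=1)
        assert total_interactions(out) == 1000

    def test_deterministic(self, rng):
        m = random_matrix(10, rng)
        g = genomic_distance_noise(m, seed=1)
        r = random_ligation_noise(m, seed=2)
        mix = NoiseMix(total_interactions(m), 0.5)
        o1 = mix_matrices(m, g, r, mix, seed=9)
        o2 = mix_matrices(m, g, r, mix, seed=9)
        np.testing.assert_array_equal(o1.counts, o2.counts)

    def test_overdraw_names_source(self):
        m, g, r = disjoint_sources(total=100)
        with pytest.raises(ValidationError, match="source G"):
            mix_matrices(m, g, r, NoiseMix(200, 1.0, g_share=1.0), seed=0)

    def test_invalid_fractions(self):
        with pytest.raises(ValidationError):
            NoiseMix(10, 1.5)
        with pytest.raises(ValidationError):
            NoiseMix(10, 0.5, g_share=-0.1)


class TestNoiseLadder:
    def test_default_has_seven_levels(self):
        assert len(DEFAULT_NOISE_LEVELS) == 7

    def test_level_zero_singleton(self, rng):
        m = random_matrix(10, rng)
        out = noise_ladder(m, levels=[0.0], seed=0)
        assert len(out) == 1
        np.testing.assert_array_equal(out[0].counts, m.counts)

    def test_totals_all_equal(self, rng):
        m = random_matrix(12, rng)
        out = noise_ladder(m, levels=[0.1, 0.3, 0.5], seed=1)
        totals = {total_interactions(x) for x in out}
        assert totals == {total_interactions(m)}

    def test_default_levels_yield_seven_matrices(self, rng):
        m = random_matrix(10, rng)
        assert len(noise_ladder(m, seed=2)) == 7
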