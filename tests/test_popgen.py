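import math
from itertools import combinations

import numpy as np
import pytest


from acdiv.popgen import (
    between_population_stats,
    fst_permutation_p,
    fu_li_D_star,
    fu_li_F_star,
    locus_summary,
    neutrality_p_value,
    nucleotide_diversity,
    segregating_sites,
    simulate_null_statistics,
    tajimas_D,
    tajimas_D_from_counts,
    watterson_theta,
)

from conftest import POP_A, POP_B, cycle_itaparica_standin, make_locus


# ---------------------------------------------------------------------------
# independent brute-force oracles (site/pair enumeration, no shared code)

def brute_stats(seqs):
    """S, eta, mean pairwise differences by direct enumeration."""
    L = len(seqs[0])
    S = eta = 0
    for j in range(L):
        col = {s[j] for s in seqs if s[j] not in "-N"}
        if len(col) >= 2:
            S += 1
            eta += len(col) - 1
    diffs = [
        sum(1 for x, y in zip(a, b) if x != y and x not in "-N" and y not in "-N")
        for a, b in combinations(seqs, 2)
    ]
    return S, eta, sum(diffs) / len(diffs)


def brute_tajima(n, S, khat):
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1, c2 = b1 - 1 / a1, b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return (khat - S / a1) / math.sqrt(c1 / a1 * S + c2 / (a1**2 + a2) * S * (S - 1))


def random_alignment(rng, n, L):
    return ["".join(rng.choice(list("ACGT"), size=L)) for _ in range(n)]


class TestWithinPopulationStats:
    def test_monomorphic(self):
        locus = make_locus(["AAAA", "AAAA", "AAAA"])
        assert segregating_sites(locus, POP_A) == (0, 0)
        assert nucleotide_diversity(locus, POP_A) == 0.0
        assert tajimas_D(locus, POP_A) is None
        assert fu_li_D_star(locus, POP_A) is None
        assert fu_li_F_star(locus, POP_A) is None

    def test_triallelic_site_counts(self):
        locus = make_locus(["AAAA", "ATAA", "AGAA"])
        assert segregating_sites(locus, POP_A) == (1, 2)

    def test_two_sequences_one_difference(self):
        locus = make_locus(["A" * 100, "T" + "A" * 99])
        assert nucleotide_diversity(locus, POP_A) == pytest.approx(0.01)
        # a1 = 1 for n=2
        assert watterson_theta(5, 2, 100) == pytest.approx(0.05)

    def test_watterson_theta_edge_cases(self):
        assert watterson_theta(0, 24, 218) == 0.0
        with pytest.raises(ValueError):
            watterson_theta(3, 1, 100)

    @pytest.mark.parametrize("seed", range(5))
    def test_brute_force_oracle_small_alignments(self, seed):
        """All per-population statistics agree with direct enumeration on
        random alignments of <=6 sequences x <=10 sites."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        L = int(rng.integers(4, 11))
        seqs = random_alignment(rng, n, L)
        locus = make_locus(seqs)
        S, eta, khat = brute_stats(seqs)
        assert segregating_sites(locus, POP_A) == (S, eta)
        assert nucleotide_diversity(locus, POP_A) == pytest.approx(khat / L)
        assert watterson_theta(eta, n, L) == pytest.approx(eta / sum(1 / i for i in range(1, n)) / L)
        if S:
            assert tajimas_D(locus, POP_A) == pytest.approx(brute_tajima(n, S, khat))

    def test_tajima_four_haplotype_example(self):
        """n=4 singleton-only case against direct constant evaluation."""
        locus = make_locus(["AAAA", "AAAT", "AATA", "ATAA"])
        S, eta, khat = brute_stats(["AAAA", "AAAT", "AATA", "ATAA"])
        assert tajimas_D(locus, POP_A) == pytest.approx(brute_tajima(4, S, khat))

    def test_tajima_zero_when_pi_matches_theta(self):
        # k_hat == S/a1 makes the numerator vanish identically
        assert tajimas_D_from_counts(6, 5, 5 / sum(1 / i for i in range(1, 6))) == (
            pytest.approx(0.0)
        )

    def test_singleton_dominated_fu_li_negative(self):
        """Every mutation private to one sequence: D* strongly negative."""
        n, S = 24, 20
        seqs = []
        for i in range(n):
            row = ["A"] * 100
            if i < S:
                row[i] = "T"
            seqs.append("".join(row))
        locus = make_locus(seqs)
        assert fu_li_D_star(locus, POP_A) < -1.0


class TestPublishedRowStandin:
    """A reconstructed 24x218 alignment whose three variable sites carry
    minor-allele counts (2, 2, 5) reproduces the printed summary row for the
    least polymorphic locus/population to all printed decimals."""

    def test_whole_fragment_statistics(self):
        locus = cycle_itaparica_standin(with_gap=True)
        s = locus_summary(locus, POP_B)
        assert s.n == 24 and s.S == 3 and s.L_effective == 217
        assert round(s.theta_w, 5) == 0.00370
        assert round(s.D_T, 5) == -0.43933
        assert round(s.D_FL, 5) == 0.97946
        assert round(s.F_FL, 5) == 0.67147

    def test_pi_with_full_length_normalization(self):
        # the printed pi normalizes by the full 218 sites
        locus = cycle_itaparica_standin(with_gap=False)
        s = locus_summary(locus, POP_B)
        assert s.L_effective == 218
        assert round(s.pi, 5) == 0.00304


class TestBetweenPopulationStats:
    def test_maximal_differentiation(self):
        a = ["A" * 100] * 4
        b = ["TT" + "A" * 98] * 4
        d = between_population_stats(make_locus(a, b), POP_A, POP_B)
        assert d.dxy == pytest.approx(0.02)
        assert d.da == pytest.approx(0.02)
        assert d.fst == pytest.approx(1.0)
        assert (d.s_shared, d.s_fixed, d.s_excl1, d.s_excl2) == (0, 2, 0, 0)

    def test_identical_populations(self):
        seqs = ["AAAA", "AATA", "ATAA", "AAAT"]
        d = between_population_stats(make_locus(seqs, seqs), POP_A, POP_B)
        # 1 - Hw/Hb gives exactly -1/(n-1) for identical finite samples
        # (within-population pairs exclude self-comparisons); no positive
        # differentiation signal may appear
        assert d.fst == pytest.approx(-1 / 3)
        assert d.fst <= 0
        assert d.s_fixed == 0

    def test_site_category_definitions(self):
        # site1 fixed, site2 shared, site3 exclusive-A, site4 exclusive-B,
        # site5 triallelic (excluded from the partition)
        a = ["ATACA", "ATTCC", "AATCG", "ATACA"]
        b = ["TTACA", "TAATA", "TTACA", "TAACA"]
        d = between_population_stats(make_locus(a, b), POP_A, POP_B)
        assert (d.s_shared, d.s_fixed, d.s_excl1, d.s_excl2) == (1, 1, 1, 1)
        assert d.s_multiallelic == 1

    @pytest.mark.parametrize("seed", range(4))
    def test_partition_conservation_and_da_bound(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = random_alignment(rng, 4, 10)
        b = random_alignment(rng, 4, 10)
        locus = make_locus(a, b)
        d = between_population_stats(locus, POP_A, POP_B)
        # conservation: categories partition the pooled biallelic sites
        pooled = 0
        for j in range(10):
            col = {s[j] for s in a + b}
            if len(col) == 2:
                pooled += 1
        assert d.s_shared + d.s_fixed + d.s_excl1 + d.s_excl2 == pooled
        assert d.da <= d.dxy + 1e-12

    def test_da_equals_dxy_iff_monomorphic_within(self):
        a = ["AAAA"] * 3
        b = ["AATT"] * 3
        d = between_population_stats(make_locus(a, b), POP_A, POP_B)
        assert d.da == pytest.approx(d.dxy)


class TestFstPermutation:
    def test_identical_populations_p_near_one(self):
        seqs = ["AAAA", "AATA", "ATAA", "AAAT"]
        p = fst_permutation_p(make_locus(seqs, seqs), POP_A, POP_B,
                              permutations=1000, seed=0)
        assert p > 0.9

    def test_maximal_differentiation_small_p(self):
        a = ["A" * 50] * 8
        b = [("T" * 5) + "A" * 45] * 8
        p = fst_permutation_p(make_locus(a, b), POP_A, POP_B,
                              permutations=2000, seed=1)
        assert p <= 0.001


class TestNeutralityPValues:
    def test_zero_statistic_is_central(self):
        res = neutrality_p_value(0.0, "tajima_d", n=16, S=8,
                                 replicates=2000, seed=3)
        assert res.p_value > 0.8

    def test_bonferroni_adjustment(self):
        res = neutrality_p_value(0.0, "tajima_d", n=10, S=5,
                                 replicates=1000, seed=4, family_size=12)
        assert res.adjusted_p == pytest.approx(min(1.0, res.p_value * 12))

    def test_replicate_floor(self):
        with pytest.raises(ValueError):
            neutrality_p_value(0.0, "tajima_d", 10, 5, replicates=100)

    def test_null_distribution_is_centered(self):
        rng = np.random.default_rng(9)
        null = simulate_null_statistics("tajima_d", 16, 10, 2000, rng)
        assert abs(null.mean()) < 0.15
        assert 0.7 < null.std() < 1.3
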