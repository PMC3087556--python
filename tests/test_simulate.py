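import numpy as np
import pytest


from acdiv.im import IMParams
from acdiv.popgen import harmonic, segregating_sites, tajimas_D
from acdiv.recombination import rm_for_locus
from acdiv.simulate import (
    CapacityError,
    SimulationConfig,
    jc_corrupt,
    misclassification_rate,
    simulate_clone_sequencing,
    simulate_im_dataset,
    simulate_with_recombination,
)

from conftest import POP_A, POP_B


class TestConfig:
    def test_defaults_mirror_study_design(self):
        cfg = SimulationConfig(seed=1)
        assert (cfg.n1, cfg.n2, cfg.loci) == (24, 24, 6)
        assert tuple(cfg.lengths) == (413, 159, 218, 269, 270, 274)
        assert cfg.truth == IMParams(5, 5, 2, 2, 0, 0)

    def test_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(n1=1)
        with pytest.raises(ValueError):
            SimulationConfig(loci=2, lengths=(100,))


class TestSimulateIMDataset:
    def test_shapes_labels_and_determinism(self):
        cfg = SimulationConfig(truth=IMParams(3, 3, 2, 1, 0.2, 0.2),
                               n1=6, n2=8, loci=2, lengths=(200, 150), seed=9)
        a = simulate_im_dataset(cfg)
        b = simulate_im_dataset(cfg)
        assert len(a.loci) == 2
        for la, lb in zip(a.loci, b.loci):
            assert [h.sequence for h in la.haplotypes] == [
                h.sequence for h in lb.haplotypes
            ]  # bit-identical under the same seed
        locus = a.loci[0]
        assert locus.n == 14 and locus.length == 200
        assert len(locus.population_sample(POP_A)) == 6
        assert len(locus.population_sample(POP_B)) == 8
        assert locus.haplotypes[0].id == "Flo01a"
        assert set(locus.haplotypes[0].sequence) <= {"A", "T"}

    def test_no_recombination_means_four_gamete_clean(self):
        for seed in range(5):
            ds = simulate_im_dataset(SimulationConfig(
                truth=IMParams(6, 6, 3, 2, 0.3, 0.3), n1=6, n2=6, loci=1,
                lengths=(300,), seed=seed))
            assert rm_for_locus(ds.loci[0]) == 0

    def test_watterson_expectation_panmictic_limit(self):
        """At t=0 the process is one deme of size thetaA: E[S] = thetaA*a1."""
        theta, n, reps = 4.0, 10, 400
        total = 0
        for seed in range(reps):
            ds = simulate_im_dataset(SimulationConfig(
                truth=IMParams(1, 1, theta, 0.0, 0, 0), n1=5, n2=5, loci=1,
                lengths=(500,), seed=10_000 + seed))
            total += segregating_sites(ds.loci[0])[0]
        expected = theta * harmonic(n)
        # 3 SE of the fixed-S-free coalescent S distribution
        var = theta * harmonic(n) + theta**2 * sum(
            1 / i**2 for i in range(1, n))
        se = (var / reps) ** 0.5
        assert abs(total / reps - expected) < 3 * se

    def test_tajima_d_unbiased_under_neutral_null(self):
        vals = []
        for seed in range(300):
            ds = simulate_im_dataset(SimulationConfig(
                truth=IMParams(1, 1, 5.0, 0.0, 0, 0), n1=5, n2=5, loci=1,
                lengths=(500,), seed=20_000 + seed))
            d = tajimas_D(ds.loci[0])
            if d is not None:
                vals.append(d)
        assert abs(np.mean(vals)) < 0.1

    def test_deep_split_regime_is_differentiated(self, deep_split_dataset):
        from acdiv.popgen import between_population_stats

        fsts, fixed = [], 0
        for locus in deep_split_dataset.loci:
            d = between_population_stats(locus, POP_A, POP_B)
            fsts.append(d.fst)
            fixed += d.s_fixed > 0
        assert np.mean(fsts) > 0.5
        assert fixed == len(deep_split_dataset.loci)

    def test_panmixia_limit_fst_near_zero(self):
        fsts = []
        from acdiv.popgen import between_population_stats

        for seed in range(20):
            ds = simulate_im_dataset(SimulationConfig(
                truth=IMParams(5, 5, 5, 0.1, 5.0, 5.0), n1=6, n2=6, loci=1,
                lengths=(400,), seed=30_000 + seed))
            fsts.append(between_population_stats(ds.loci[0], POP_A, POP_B).fst)
        assert abs(np.mean(fsts)) < 0.15

    def test_capacity_error_on_short_locus(self):
        with pytest.raises(CapacityError):
            simulate_im_dataset(SimulationConfig(
                truth=IMParams(50, 50, 50, 10, 0, 0), n1=12, n2=12, loci=1,
                lengths=(10,), seed=1))


class TestRecombinationBackend:
    def test_rho_zero_passthrough_identical(self):
        cfg = SimulationConfig(truth=IMParams(4, 4, 2, 1, 0, 0), n1=4, n2=4,
                               loci=1, lengths=(200,), seed=77)
        a = simulate_im_dataset(cfg)
        b = simulate_with_recombination(cfg)
        assert [h.sequence for h in a.loci[0].haplotypes] == [
            h.sequence for h in b.loci[0].haplotypes
        ]

    def test_high_rho_usually_violates_four_gametes(self):
        hits = 0
        reps = 20
        for seed in range(reps):
            ds = simulate_with_recombination(SimulationConfig(
                truth=IMParams(10, 10, 5, 2, 0, 0), n1=12, n2=12, loci=1,
                lengths=(300,), recombination_rate=20, seed=500 + seed))
            hits += rm_for_locus(ds.loci[0]) > 0
        assert hits >= 0.9 * reps


class TestCloneSequencing:
    def test_rate_matches_closed_form(self):
        obs, truth = simulate_clone_sequencing(10_000, 1.0, 8, seed=42)
        rate = misclassification_rate(obs, truth)
        p = 0.5**7
        se = (p * (1 - p) / 10_000) ** 0.5
        assert abs(rate - p) < 3 * se

    def test_degenerate_cases(self):
        obs, truth = simulate_clone_sequencing(500, 0.0, 8, seed=1)
        assert misclassification_rate(obs, truth) == 0.0
        obs, truth = simulate_clone_sequencing(500, 1.0, 1, seed=2)
        assert misclassification_rate(obs, truth) == 1.0


def test_jc_corrupt_breaks_binary_coding():
    ds = simulate_im_dataset(SimulationConfig(
        truth=IMParams(3, 3, 2, 1, 0, 0), n1=4, n2=4, loci=1,
        lengths=(300,), seed=3))
    noisy = jc_corrupt(ds.loci[0], extra_rate=0.05, seed=4)
    bases = set("".join(h.sequence for h in noisy.haplotypes))
    assert len(bases) > 2
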