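import collections
import math

import numpy as np
import pytest
from scipy.stats import chisquare

from hybridest import (
    GenomeModel,
    SimulationConfig,
    meiosis_linked,
    sample_markers,
    simulate_continent_island,
    simulate_cross,
    simulate_intermixture,
    true_indices,
)


class TestIntermixture:
    def test_founders_are_pure(self):
        run = simulate_intermixture(
            SimulationConfig(N=40, mu=0.3, generations=0, loci=10, seed=1)
        )
        assert len(run.generations) == 1
        pops = collections.Counter()
        for ind in run.generations[0]:
            idx = ind.true_indices()
            assert idx.H_I == 0.0
            assert idx.S in (0.0, 1.0)
            pops[idx.S] += 1
        assert pops[0.0] == 12  # round(0.3 * 40) pure population-1 founders

    def test_generation_one_class_frequencies(self):
        """With mu=0.5, generation-1 offspring are P1, F1, P2 in Hardy-
        Weinberg-like proportions (0.25, 0.5, 0.25) up to binomial noise."""
        N = 1000
        run = simulate_intermixture(
            SimulationConfig(N=N, mu=0.5, generations=1, loci=10, seed=2)
        )
        counts = collections.Counter()
        for ind in run.generations[1]:
            idx = ind.true_indices()
            if idx.S == 0.0:
                counts["P1"] += 1
            elif idx.S == 1.0:
                counts["P2"] += 1
            elif idx.H_I == 1.0:
                counts["F1"] += 1
        for cls, p in (("P1", 0.25), ("F1", 0.5), ("P2", 0.25)):
            se = math.sqrt(p * (1 - p) / N)
            assert abs(counts[cls] / N - p) <= 3 * se

    def test_mean_ancestry_is_a_drift_martingale(self):
        """Without immigration the expected population-mean S is constant
        across generations (allele tags drift but do not trend)."""
        means0, means5 = [], []
        for rep in range(100):
            run = simulate_intermixture(
                SimulationConfig(N=50, mu=0.5, generations=5, loci=20, seed=3000 + rep)
            )
            means0.append(np.mean([i.true_indices().S for i in run.generations[0]]))
            means5.append(np.mean([i.true_indices().S for i in run.generations[5]]))
        assert np.mean(means0) == pytest.approx(0.5, abs=1e-12)
        assert np.mean(means5) == pytest.approx(0.5, abs=0.03)

    def test_heterozygosity_decays_under_drift(self):
        run = simulate_intermixture(
            SimulationConfig(N=30, mu=0.5, generations=150, loci=30, seed=4)
        )
        h_early = np.mean([i.true_indices().H_I for i in run.generations[2]])
        h_late = np.mean([i.true_indices().H_I for i in run.generations[150]])
        s_late = np.mean([i.true_indices().S for i in run.generations[150]])
        assert h_late < h_early / 2
        assert 0.0 <= s_late <= 1.0

    def test_reproducible_bit_for_bit(self):
        cfg = SimulationConfig(N=30, mu=0.4, generations=3, loci=15, seed=77)
        a = simulate_intermixture(cfg)
        b = simulate_intermixture(cfg)
        for ga, gb in zip(a.generations, b.generations):
            for ia, ib in zip(ga, gb):
                assert np.array_equal(ia.tags, ib.tags)
                assert np.array_equal(ia.alleles, ib.alleles)

    def test_tag_conservation(self):
        """Offspring tags at each locus are one tag from each parent's
        genome: totals per generation stay within founding bounds."""
        run = simulate_intermixture(
            SimulationConfig(N=20, mu=0.5, generations=3, loci=5, seed=8)
        )
        for gen in run.generations:
            tags = np.stack([i.tags for i in gen])
            assert set(np.unique(tags)) <= {1, 2}


class TestContinentIsland:
    def test_m_zero_reduces_to_intermixture(self):
        cfg = SimulationConfig(N=50, mu=0.5, m=0.0, generations=5, loci=10, seed=9)
        ci = simulate_continent_island(cfg)
        im = simulate_intermixture(cfg)
        for ga, gb in zip(ci.generations, im.generations):
            for ia, ib in zip(ga, gb):
                assert np.array_equal(ia.tags, ib.tags)

    def test_expected_immigrant_count_is_Nm(self):
        run = simulate_continent_island(
            SimulationConfig(N=100, mu=0.5, m=0.10, generations=30, loci=5, seed=10)
        )
        mean_imm = np.mean(run.immigrants[1:])
        assert mean_imm == pytest.approx(10.0, abs=2.0)
        # post-dispersal populations actually contain the replacements
        assert run.post_dispersal is not None

    def test_immigration_inflates_ancestry_variance(self):
        """Recurrent immigration (Nm=10) keeps extreme genotypes in the
        population, so the cross-sectional variance of S at generation 10
        exceeds the closed-swarm variance (paired seeds, 20 replicates)."""
        var_ci, var_im = [], []
        for rep in range(20):
            ci = simulate_continent_island(
                SimulationConfig(N=100, m=0.10, generations=10, loci=30, seed=500 + rep)
            )
            im = simulate_intermixture(
                SimulationConfig(N=100, m=0.0, generations=10, loci=30, seed=500 + rep)
            )
            var_ci.append(np.var([i.true_indices().S for i in ci.generations[10]]))
            var_im.append(np.var([i.true_indices().S for i in im.generations[10]]))
        assert np.mean(var_ci) > np.mean(var_im)


class TestCrosses:
    def test_f1_is_fully_heterozygous(self):
        for ind in simulate_cross("F1", n_loci=50, n_individuals=5, seed=0):
            idx = ind.true_indices()
            assert (idx.S, idx.H_I) == (0.5, 1.0)

    def test_unlinked_f2_mendelian_heterozygosity(self):
        inds = simulate_cross("F2", n_loci=400, n_individuals=1000, seed=1)
        h = np.array([i.true_indices().H_I for i in inds])
        se = math.sqrt(0.5 * 0.5 / (400 * 1000))
        assert abs(h.mean() - 0.5) <= 3 * se * math.sqrt(1000)  # conservative

    def test_linked_f2_has_inflated_individual_variance(self):
        linked = simulate_cross("F2", genome=GenomeModel(), n_individuals=1000, seed=2)
        unlinked = simulate_cross("F2", n_loci=400, n_individuals=1000, seed=2)
        hl = np.array([i.true_indices().H_I for i in linked])
        hu = np.array([i.true_indices().H_I for i in unlinked])
        assert hl.mean() == pytest.approx(0.5, abs=0.02)
        assert hl.var() > hu.var()

    def test_backcross_expectations(self):
        b1 = simulate_cross("B1", n_loci=400, n_individuals=1000, seed=3)
        s = np.array([i.true_indices().S for i in b1])
        h = np.array([i.true_indices().H_I for i in b1])
        assert s.mean() == pytest.approx(0.25, abs=0.01)
        # per-individual H_I concentrates around 0.5 at 400 unlinked loci
        assert np.mean((h >= 0.4) & (h <= 0.6)) >= 0.99

    def test_unknown_cross_label(self):
        with pytest.raises(ValueError, match="cross"):
            simulate_cross("F11", n_loci=10, n_individuals=1, seed=0)
        with pytest.raises(ValueError):
            simulate_cross("BC2", n_loci=10, n_individuals=1, seed=0)


class TestMeiosis:
    def test_homozygous_parent_gamete_is_either_homolog(self):
        # a fully homozygous parent transmits the same haplotype whatever
        # the breakpoints
        hom = simulate_cross("F1", genome=GenomeModel(), n_individuals=1, seed=0)[0]
        import hybridest.simulate as sim

        homo = sim.SimulatedIndividual(
            np.full((400, 2), 2, dtype=np.int8),
            np.full((400, 2), 1, dtype=np.int16),
            hom.loci, hom._allele_names,
        )
        gt, _ = meiosis_linked(homo, GenomeModel(), np.random.default_rng(6))
        assert (gt == 2).all()

    def test_adjacent_locus_recombination_fraction_is_2cM(self):
        gm = GenomeModel()
        f1 = simulate_cross("F1", genome=gm, n_individuals=1, seed=0)[0]
        rng = np.random.default_rng(11)
        n = 4000
        switches = 0
        for _ in range(n):
            gt, _ = meiosis_linked(f1, gm, rng)
            switches += gt[0] != gt[1]
        p = switches / n
        se = math.sqrt((1 / 49) * (48 / 49) / n)
        assert abs(p - 1 / 49) <= 3 * se

    def test_breakpoints_uniform_across_arm_intervals(self):
        """With exactly one crossover per arm, each of the 49 inter-locus
        intervals on an arm receives the breakpoint equally often."""
        gm = GenomeModel()
        f1 = simulate_cross("F1", genome=gm, n_individuals=1, seed=0)[0]
        rng = np.random.default_rng(12)
        counts = np.zeros(49)
        n = 10000
        for _ in range(n):
            gt, _ = meiosis_linked(f1, gm, rng)
            arm = gt[:50]
            sw = np.flatnonzero(arm[:-1] != arm[1:])
            assert len(sw) == 1  # heterozygous parent: switch is visible
            counts[sw[0]] += 1
        assert counts.sum() == n
        assert chisquare(counts).pvalue > 1e-4


class TestSampleMarkers:
    def test_systematic_10cm_is_every_fifth_locus(self):
        gm = GenomeModel()
        idx = sample_markers(gm, 60, "systematic-10cM", seed=3)
        diffs = np.diff(np.sort(idx))
        assert set(np.unique(diffs)) <= {5, 5 + 400 - 60 * 5}
        idx2 = sample_markers(gm, 60, "systematic-2cM", seed=3)
        assert len(np.unique(idx2)) == 60

    def test_full_random_draw_is_all_loci(self):
        idx = sample_markers(400, 400, "random", seed=0)
        assert np.array_equal(np.sort(idx), np.arange(400))

    def test_seed_contract(self):
        gm = GenomeModel()
        a = sample_markers(gm, 60, "random", seed=1)
        b = sample_markers(gm, 60, "random", seed=2)
        assert not np.array_equal(a, b)
        # systematic draws differ only in starting offset
        s1 = sample_markers(gm, 30, "systematic-10cM", seed=1)
        s2 = sample_markers(gm, 30, "systematic-10cM", seed=2)
        assert set(np.diff(s1) % 400) == set(np.diff(s2) % 400) == {5}

    def test_oversized_requests_rejected(self):
        with pytest.raises(ValueError):
            sample_markers(400, 401, "random", seed=0)
        with pytest.raises(ValueError, match="revisits"):
            sample_markers(GenomeModel(), 90, "systematic-10cM", seed=0)


class TestTrueIndices:
    def test_pure_and_f1_corners(self):
        f1 = simulate_cross("F1", n_loci=10, n_individuals=1, seed=0)[0]
        assert (f1.true_indices().S, f1.true_indices().H_I) == (0.5, 1.0)
        run = simulate_intermixture(
            SimulationConfig(N=4, mu=0.0, generations=0, loci=10, seed=0)
        )
        p2 = run.generations[0][0]
        assert (true_indices(p2).S, true_indices(p2).H_I) == (1.0, 0.0)

    def test_subset_restriction(self):
        f2 = simulate_cross("F2", n_loci=40, n_individuals=1, seed=9)[0]
        full = f2.true_indices()
        sub = f2.true_indices(subset=np.arange(10))
        het10 = (f2.tags[:10, 0] != f2.tags[:10, 1]).mean()
        assert sub.H_I == het10
        assert 0 <= full.S <= 1
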