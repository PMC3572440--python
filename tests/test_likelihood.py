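import itertools
import math

import numpy as np
import pytest

from hybridest import (
    LOG_IMPOSSIBLE,
    AlleleFrequencyTable,
    CodominantGenotype,
    DominantPhenotype,
    GenomicProportions,
    HybridIndices,
    UnknownAlleleError,
    closed_form_mle_diagnostic,
    genotype_prob_codominant,
    genotype_prob_generalA,
    indices_to_proportions,
    loglik_codominant,
    loglik_dominant,
    proportions_to_indices,
)

from conftest import genotype_from_counts

F1 = GenomicProportions(0.0, 1.0, 0.0)
F2 = GenomicProportions(0.25, 0.5, 0.25)
P1 = GenomicProportions(1.0, 0.0, 0.0)


class TestGenotypeProbCodominant:
    @pytest.mark.parametrize(
        "freqs, pair, theta, expected",
        [
            # an F1 at a fixed difference is heterozygous with certainty
            ({"1": (1.0, 0.0), "2": (0.0, 1.0)}, ("1", "2"), F1, 1.0),
            # pure population 1, homozygote probability is f_j1 squared
            ({"A": (0.8, 0.2), "a": (0.2, 0.8)}, ("A", "A"), P1, 0.64),
            # F2 heterozygote at a 0.9/0.1 locus: each F1 gamete carries
            # allele A with probability (0.9 + 0.1)/2 = 0.5, so 2*0.5*0.5
            ({"A": (0.9, 0.1), "a": (0.1, 0.9)}, ("A", "a"), F2, 0.50),
        ],
    )
    def test_known_values(self, freqs, pair, theta, expected):
        assert genotype_prob_codominant(freqs, pair, theta) == pytest.approx(expected)

    def test_unknown_allele_raises(self):
        with pytest.raises(KeyError):
            genotype_prob_codominant({"A": (1.0, 0.0)}, ("A", "Z"), F1)

    @pytest.mark.parametrize("n_alleles", [2, 3, 5])
    @pytest.mark.parametrize("trial", range(3))
    def test_normalization_over_all_pairs(self, n_alleles, trial, rng):
        """Genotype probabilities sum to 1 over all unordered allele pairs
        for any allele count and any point on the simplex."""
        names = [f"a{i}" for i in range(n_alleles)]
        f1 = rng.dirichlet(np.ones(n_alleles))
        f2 = rng.dirichlet(np.ones(n_alleles))
        freqs = {n: (f1[i], f2[i]) for i, n in enumerate(names)}
        theta = GenomicProportions.from_array(rng.dirichlet([1.0, 1.0, 1.0]))
        total = sum(
            genotype_prob_codominant(freqs, pair, theta)
            for pair in itertools.combinations_with_replacement(names, 2)
        )
        assert total == pytest.approx(1.0, abs=1e-9)


class TestGenotypeProbGeneralA:
    def test_two_pool_reduction_matches_codominant(self, rng):
        for _ in range(20):
            f1, f2 = rng.random(2)
            freqs = {"A": (f1, f2), "a": (1 - f1, 1 - f2)}
            p = rng.dirichlet([1.0, 1.0, 1.0])
            theta = GenomicProportions.from_array(p)
            props = {(1, 1): p[0], (1, 2): p[1], (2, 2): p[2]}
            for pair in [("A", "A"), ("A", "a"), ("a", "a")]:
                assert genotype_prob_generalA(freqs, pair, props) == pytest.approx(
                    genotype_prob_codominant(freqs, pair, theta), abs=1e-14
                )

    def test_three_pool_values(self):
        freqs = {"j": (0.5, 0.6, 0.0), "k": (0.5, 0.4, 1.0)}
        # all ancestry from pool 1: homozygote prob is f_j1^2
        assert genotype_prob_generalA(
            freqs, ("j", "j"), {(1, 1): 1.0, (1, 2): 0.0, (2, 2): 0.0, (3, 3): 0.0}
        ) == pytest.approx(0.25)
        # one copy from pool 1, one from pool 2
        freqs2 = {"j": (0.6, 0.5, 0.0), "k": (0.4, 0.5, 1.0)}
        assert genotype_prob_generalA(
            freqs2, ("j", "j"), {(1, 2): 1.0}
        ) == pytest.approx(0.30)

    def test_unnormalized_proportions_raise(self):
        with pytest.raises(ValueError, match="sum"):
            genotype_prob_generalA(
                {"j": (1.0, 0.0)}, ("j", "j"), {(1, 1): 0.4, (2, 2): 0.4}
            )


class TestLoglikCodominant:
    def test_all_het_diagnostic_under_f1_is_zero(self, diag3):
        g = CodominantGenotype({l: ("1", "2") for l in diag3.loci})
        assert loglik_codominant(g, diag3, F1) == 0.0

    def test_single_homozygote_under_f2(self, diag3):
        g = CodominantGenotype({diag3.loci[0]: ("1", "1")})
        assert loglik_codominant(g, diag3, F2) == pytest.approx(math.log(0.25))

    def test_impossible_genotype_hits_sentinel(self, diag3):
        g = CodominantGenotype({diag3.loci[0]: ("1", "1")})
        assert loglik_codominant(g, diag3, F1) == LOG_IMPOSSIBLE

    def test_missing_loci_drop_from_sum(self, diag3):
        g = CodominantGenotype(
            {diag3.loci[0]: ("1", "1"), diag3.loci[1]: None, diag3.loci[2]: None}
        )
        assert g.n == 1
        assert loglik_codominant(g, diag3, F2) == pytest.approx(math.log(0.25))

    def test_all_missing_raises(self, diag3):
        g = CodominantGenotype({l: None for l in diag3.loci})
        with pytest.raises(ValueError, match="non-missing"):
            loglik_codominant(g, diag3, F2)

    def test_invariance_under_locus_and_pair_order(self, rng):
        table = AlleleFrequencyTable.biallelic(8, 0.9, 0.2)
        loci = list(table.loci)
        pairs = [tuple(rng.choice(["A", "a"], 2)) for _ in loci]
        g = CodominantGenotype(dict(zip(loci, pairs)))
        perm = list(rng.permutation(loci))
        g_perm = CodominantGenotype(
            {l: tuple(reversed(g.calls[l])) for l in perm}
        )
        theta = GenomicProportions.from_array(rng.dirichlet([1, 1, 1]))
        assert loglik_codominant(g, table, theta) == pytest.approx(
            loglik_codominant(g_perm, table, theta), abs=1e-12
        )


class TestLoglikDominant:
    def test_band_present_pure_parental(self):
        table = AlleleFrequencyTable.biallelic(1, 0.9, 0.1, dominant=True)
        ph = DominantPhenotype({table.loci[0]: 1}, table.dominant_alleles)
        assert loglik_dominant(ph, table, P1) == pytest.approx(math.log(0.99))

    def test_band_absent_diagnostic_f1_impossible(self):
        table = AlleleFrequencyTable.biallelic(1, 1.0, 0.0, dominant=True)
        ph = DominantPhenotype({table.loci[0]: 0}, table.dominant_alleles)
        assert loglik_dominant(ph, table, F1) == LOG_IMPOSSIBLE

    def test_band_absent_f2(self):
        # recessive allele frequencies 0.1 (pop1) and 0.9 (pop2):
        # Pr(k,k) = 0.25*0.01 + 0.5*0.09 + 0.25*0.81 = 0.25
        table = AlleleFrequencyTable.biallelic(1, 0.9, 0.1, dominant=True)
        ph = DominantPhenotype({table.loci[0]: 0}, table.dominant_alleles)
        assert loglik_dominant(ph, table, F2) == pytest.approx(math.log(0.25))

    def test_non_binary_band_rejected(self):
        with pytest.raises(ValueError, match="band state"):
            DominantPhenotype({"m1": 2}, {"m1": "A"})

    def test_zero_frequency_recessive_gives_flat_likelihood(self, rng):
        """With the recessive allele absent from both populations the band
        is always present and the dominant likelihood is flat at 0, exactly
        matching the collapsed codominant likelihood."""
        table = AlleleFrequencyTable(
            {"m1": {"A": (1.0, 1.0), "a": (0.0, 0.0)}},
            dominant_alleles={"m1": "A"},
        )
        ph = DominantPhenotype({"m1": 1}, {"m1": "A"})
        g = CodominantGenotype({"m1": ("A", "A")})
        for _ in range(5):
            theta = GenomicProportions.from_array(rng.dirichlet([1, 1, 1]))
            assert loglik_dominant(ph, table, theta) == pytest.approx(0.0)
            assert loglik_codominant(g, table, theta) == pytest.approx(0.0)


class TestClosedFormMle:
    def test_f2_like_fractions(self):
        table = AlleleFrequencyTable.diagnostic(4)
        g = genotype_from_counts(table, 1, 2, 1)
        idx = closed_form_mle_diagnostic(g, table)
        assert (idx.S, idx.H_I) == (0.5, 0.5)

    def test_all_homozygous_pop2(self, diag3):
        g = genotype_from_counts(diag3, 0, 0, 3)
        idx = closed_form_mle_diagnostic(g, diag3)
        assert (idx.S, idx.H_I) == (1.0, 0.0)

    def test_65_locus_counts(self, diag65):
        g = genotype_from_counts(diag65, 30, 20, 15)
        idx = closed_form_mle_diagnostic(g, diag65)
        assert idx.H_I == pytest.approx(20 / 65)
        assert idx.S == pytest.approx(25 / 65)

    def test_matches_fine_grid_argmax(self, diag65):
        """The closed form sits at the arg-max of the joint log-likelihood
        over a fine lattice (independent exhaustive-search oracle)."""
        from hybridest.likelihood import codominant_coefficients, loglik_from_coefficients

        g = genotype_from_counts(diag65, 30, 20, 15)
        coef, _ = codominant_coefficients(g, diag65)
        ss = np.arange(0, 1.0001, 1e-3)
        best = (-np.inf, None)
        for h in np.arange(0, 1.0001, 1e-2):
            s_ok = ss[(h <= 2 * np.minimum(ss, 1 - ss) + 1e-12)]
            thetas = np.column_stack([1 - s_ok - h / 2, np.full(len(s_ok), h), s_ok - h / 2])
            lls = loglik_from_coefficients(coef, np.clip(thetas, 0, None))
            i = int(np.argmax(lls))
            if lls[i] > best[0]:
                best = (lls[i], (s_ok[i], h))
        idx = closed_form_mle_diagnostic(g, diag65)
        assert best[1][0] == pytest.approx(idx.S, abs=2e-3)
        assert best[1][1] == pytest.approx(idx.H_I, abs=1e-2)

    def test_non_diagnostic_locus_rejected(self):
        table = AlleleFrequencyTable.biallelic(2, 0.9, 0.1)
        g = CodominantGenotype({l: ("A", "a") for l in table.loci})
        with pytest.raises(ValueError, match="MCMC"):
            closed_form_mle_diagnostic(g, table)


class TestConversions:
    @pytest.mark.parametrize(
        "s, h, theta",
        [
            (0.0, 0.0, (1.0, 0.0, 0.0)),   # P1
            (1.0, 0.0, (0.0, 0.0, 1.0)),   # P2
            (0.5, 1.0, (0.0, 1.0, 0.0)),   # F1
            (0.5, 0.5, (0.25, 0.5, 0.25)), # F2
            (0.25, 0.5, (0.5, 0.5, 0.0)),  # B1
            (0.75, 0.5, (0.0, 0.5, 0.5)),  # B2
        ],
    )
    def test_six_class_points_round_trip_exactly(self, s, h, theta):
        gp = indices_to_proportions(HybridIndices(s, h))
        assert (gp.p11, gp.p12, gp.p22) == theta
        back = proportions_to_indices(gp)
        assert (back.S, back.H_I) == (s, h)

    def test_round_trip_random_points(self, rng):
        for _ in range(50):
            s = rng.random()
            h = rng.random() * 2 * min(s, 1 - s)
            idx = HybridIndices(s, h)
            back = proportions_to_indices(indices_to_proportions(idx))
            assert back.S == pytest.approx(s, abs=1e-12)
            assert back.H_I == h

    def test_outside_triangle_rejected(self):
        with pytest.raises(ValueError, match="triangular"):
            HybridIndices(0.1, 0.9)
        with pytest.raises(ValueError):
            GenomicProportions(0.5, 0.5, 0.5)


class TestAlleleFrequencyTable:
    def test_sum_violation_names_locus(self):
        with pytest.raises(ValueError, match="bad_locus"):
            AlleleFrequencyTable({"bad_locus": {"A": (0.6, 0.5), "a": (0.3, 0.5)}})

    def test_diagnostic_detection(self, diag3):
        assert diag3.all_diagnostic()
        table = AlleleFrequencyTable.biallelic(1, 0.999999999, 0.0)
        assert not table.all_diagnostic()

    def test_unknown_allele_names_locus_and_allele(self, diag3):
        locus = diag3.loci[0]
        with pytest.raises(UnknownAlleleError) as exc:
            loglik_codominant(
                CodominantGenotype({locus: ("1", "weird")}), diag3, F2
            )
        assert exc.value.locus == locus
        assert exc.value.allele == "weird"
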