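"""Genotype probabilities and log-likelihoods for two-way hybrids.

The genomic composition of a diploid hybrid between two ancestral
populations is summarized by three genomic proportions: ``p11`` (loci with
both allele copies derived from population 1), ``p12`` (loci with one copy
from each population) and ``p22`` (both copies from population 2).  The two
familiar summaries of hybridity are linear in these proportions:

* ancestry index ``S = p22 + p12/2`` -- the fraction of allele copies
  derived from population 2 (so S=0 is pure population 1, S=1 pure
  population 2), and
* interclass heterozygosity ``H_I = p12`` -- the fraction of loci carrying
  one allele from each ancestral population.

Given the allele frequencies of the two ancestral populations (treated as
known constants), the probability of an observed single-locus genotype is a
mixture over the three proportions, and the log-likelihood of a multilocus
genotype is the sum of the per-locus log-probabilities.  This module
provides those probabilities for codominant and dominant (band
presence/absence) markers, the general-A ancestral-pool extension, the
closed-form maximum-likelihood estimator available when all markers are
diagnostic, and conversions between genomic proportions and (S, H_I).
"""

from __future__ import annotations

import dataclasses
import math
from collections import Counter
from collections.abc import Mapping, Sequence
from typing import Optional

import numpy as np

__all__ = [
    "LOG_IMPOSSIBLE",
    "UnknownAlleleError",
    "GenomicProportions",
    "HybridIndices",
    "AlleleFrequencyTable",
    "CodominantGenotype",
    "DominantPhenotype",
    "genotype_prob_codominant",
    "genotype_prob_generalA",
    "loglik_codominant",
    "loglik_dominant",
    "closed_form_mle_diagnostic",
    "indices_to_proportions",
    "proportions_to_indices",
    "impossible_loci",
    "codominant_coefficients",
    "dominant_coefficients",
    "loglik_from_coefficients",
]

#: Finite, representable stand-in for ln(0).  Using a large negative float
#: instead of -inf keeps arithmetic well defined in the sampler (differences
#: of two impossible states are 0, not nan) while guaranteeing that any
#: possible state beats any impossible one.
LOG_IMPOSSIBLE = -1e308

_SIMPLEX_TOL = 1e-9
_TRIANGLE_TOL = 1e-9
_FREQ_SUM_TOL = 1e-6
_DIAGNOSTIC_TOL = 1e-12


class UnknownAlleleError(KeyError):
    """An observed allele is absent from the frequency table."""

    def __init__(self, locus: object, allele: object):
        super().__init__(
            f"allele {allele!r} at locus {locus!r} is not defined in the "
            "allele frequency table for every ancestral population"
        )
        self.locus = locus
        self.allele = allele


@dataclasses.dataclass(frozen=True)
class GenomicProportions:
    """A point (p11, p12, p22) on the 2-simplex of genomic proportions."""

    p11: float
    p12: float
    p22: float

    def __post_init__(self):
        comps = (self.p11, self.p12, self.p22)
        for name, value in zip(("p11", "p12", "p22"), comps):
            if not (-_SIMPLEX_TOL <= value <= 1.0 + _SIMPLEX_TOL):
                raise ValueError(
                    f"genomic proportion {name}={value!r} outside [0, 1]"
                )
        total = self.p11 + self.p12 + self.p22
        if abs(total - 1.0) > _SIMPLEX_TOL:
            raise ValueError(
                f"genomic proportions sum to {total!r}, expected 1 "
                f"(tolerance {_SIMPLEX_TOL})"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.p11, self.p12, self.p22], dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "GenomicProportions":
        p11, p12, p22 = (float(x) for x in arr)
        return cls(p11, p12, p22)


@dataclasses.dataclass(frozen=True)
class HybridIndices:
    """Ancestry index S (fraction of population-2 alleles) and H_I.

    The pair is constrained to the triangular sample space
    ``H_I <= 2 * min(S, 1 - S)``: an individual with ancestry S cannot be
    heterozygous for foreign alleles at more loci than twice its minority
    ancestry fraction.
    """

    S: float
    H_I: float

    def __post_init__(self):
        if not (-_TRIANGLE_TOL <= self.S <= 1.0 + _TRIANGLE_TOL):
            raise ValueError(f"ancestry index S={self.S!r} outside [0, 1]")
        if not (-_TRIANGLE_TOL <= self.H_I <= 1.0 + _TRIANGLE_TOL):
            raise ValueError(
                f"interclass heterozygosity H_I={self.H_I!r} outside [0, 1]"
            )
        if self.H_I > 2.0 * min(self.S, 1.0 - self.S) + _TRIANGLE_TOL:
            raise ValueError(
                f"(S={self.S!r}, H_I={self.H_I!r}) outside the triangular "
                "sample space H_I <= 2*min(S, 1-S)"
            )


def indices_to_proportions(idx: HybridIndices) -> GenomicProportions:
    """Map (S, H_I) to genomic proportions (p11, p12, p22)."""
    p12 = idx.H_I
    p22 = idx.S - 0.5 * idx.H_I
    p11 = 1.0 - idx.S - 0.5 * idx.H_I
    # triangle-boundary points can land a few ulp below zero
    if -_TRIANGLE_TOL <= p22 < 0.0:
        p22 = 0.0
    if -_TRIANGLE_TOL <= p11 < 0.0:
        p11 = 0.0
    return GenomicProportions(p11, p12, p22)


def proportions_to_indices(theta: GenomicProportions) -> HybridIndices:
    """Map genomic proportions to (S, H_I)."""
    return HybridIndices(S=theta.p22 + 0.5 * theta.p12, H_I=theta.p12)


class AlleleFrequencyTable:
    """Allele frequencies per locus per ancestral population.

    Parameters
    ----------
    frequencies
        Mapping ``locus -> {allele -> per-population frequencies}``.  The
        per-population vector must have one entry per ancestral population
        (A >= 2), in the order given by ``populations``.  Locus order is the
        insertion order of the mapping and defines the locus register.
    populations
        Names of the ancestral populations; its length fixes A.
    dominant_alleles
        Optional mapping ``locus -> allele`` naming the dominant allele at
        markers scored as dominant (band presence/absence).
    """

    def __init__(
        self,
        frequencies: Mapping[str, Mapping[str, Sequence[float]]],
        populations: Sequence[str] = ("pop1", "pop2"),
        dominant_alleles: Optional[Mapping[str, str]] = None,
    ):
        self.populations = tuple(str(p) for p in populations)
        if len(self.populations) < 2:
            raise ValueError("at least two ancestral populations are required")
        self._freq: dict[str, dict[str, np.ndarray]] = {}
        for locus, alleles in frequencies.items():
            if not alleles:
                raise ValueError(f"locus {locus!r} has no alleles")
            table: dict[str, np.ndarray] = {}
            for allele, f in alleles.items():
                vec = np.asarray(f, dtype=float)
                if vec.shape != (len(self.populations),):
                    raise ValueError(
                        f"locus {locus!r} allele {allele!r}: expected "
                        f"{len(self.populations)} frequencies, got {vec.shape}"
                    )
                if np.any(vec < -_SIMPLEX_TOL) or np.any(vec > 1 + _SIMPLEX_TOL):
                    raise ValueError(
                        f"locus {locus!r} allele {allele!r}: frequency outside [0, 1]"
                    )
                table[str(allele)] = np.clip(vec, 0.0, 1.0)
            sums = np.sum(list(table.values()), axis=0)
            if np.any(np.abs(sums - 1.0) > _FREQ_SUM_TOL):
                bad = self.populations[int(np.argmax(np.abs(sums - 1.0)))]
                raise ValueError(
                    f"allele frequencies at locus {locus!r} sum to "
                    f"{sums.tolist()} (population {bad!r} violates the "
                    f"sum-to-1 constraint at tolerance {_FREQ_SUM_TOL})"
                )
            self._freq[str(locus)] = table
        self.dominant_alleles = dict(dominant_alleles or {})

    # -- construction helpers -------------------------------------------------

    @classmethod
    def diagnostic(
        cls,
        loci: int | Sequence[str],
        alleles: tuple[str, str] = ("1", "2"),
    ) -> "AlleleFrequencyTable":
        """Table of diagnostic loci: allele ``alleles[0]`` fixed in
        population 1 and ``alleles[1]`` fixed in population 2."""
        if isinstance(loci, int):
            loci = [f"L{i + 1:03d}" for i in range(loci)]
        a1, a2 = alleles
        return cls(
            {locus: {a1: (1.0, 0.0), a2: (0.0, 1.0)} for locus in loci}
        )

    @classmethod
    def biallelic(
        cls,
        loci: Sequence[str] | int,
        f_pop1: float | Sequence[float],
        f_pop2: float | Sequence[float],
        alleles: tuple[str, str] = ("A", "a"),
        dominant: bool = False,
    ) -> "AlleleFrequencyTable":
        """Biallelic table where allele ``alleles[0]`` has frequency
        ``f_pop1`` in population 1 and ``f_pop2`` in population 2 (scalars
        broadcast over loci).  With ``dominant=True`` the first allele is
        registered as dominant at every marker."""
        if isinstance(loci, int):
            loci = [f"L{i + 1:03d}" for i in range(loci)]
        loci = list(loci)
        f1 = np.broadcast_to(np.asarray(f_pop1, float), (len(loci),))
        f2 = np.broadcast_to(np.asarray(f_pop2, float), (len(loci),))
        a, b = alleles
        freqs = {
            locus: {a: (f1[i], f2[i]), b: (1.0 - f1[i], 1.0 - f2[i])}
            for i, locus in enumerate(loci)
        }
        dom = {locus: a for locus in loci} if dominant else None
        return cls(freqs, dominant_alleles=dom)

    # -- accessors ------------------------------------------------------------

    @property
    def loci(self) -> tuple[str, ...]:
        return tuple(self._freq)

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    def alleles(self, locus: str) -> tuple[str, ...]:
        try:
            return tuple(self._freq[locus])
        except KeyError:
            raise KeyError(f"locus {locus!r} not in frequency table") from None

    def lookup(self, locus: str, allele: str) -> np.ndarray:
        table = self._freq.get(locus)
        if table is None:
            raise KeyError(f"locus {locus!r} not in frequency table")
        vec = table.get(allele)
        if vec is None:
            raise UnknownAlleleError(locus, allele)
        return vec

    def frequencies(self, locus: str) -> dict[str, np.ndarray]:
        if locus not in self._freq:
            raise KeyError(f"locus {locus!r} not in frequency table")
        return dict(self._freq[locus])

    def is_diagnostic(self, locus: str, tol: float = _DIAGNOSTIC_TOL) -> bool:
        """True if every allele at ``locus`` is literally fixed (frequency 1)
        in exactly one of two ancestral populations and absent elsewhere."""
        if self.n_populations != 2:
            return False
        for vec in self._freq[locus].values():
            fixed = np.abs(vec - 1.0) <= tol
            absent = np.abs(vec) <= tol
            if not (fixed.sum() == 1 and (fixed | absent).all()):
                return False
        return True

    def all_diagnostic(self, loci: Optional[Sequence[str]] = None) -> bool:
        return all(self.is_diagnostic(l) for l in (loci or self.loci))

    def population_allele(self, locus: str, population_index: int) -> str:
        """The allele fixed in the given population (diagnostic loci only)."""
        for allele, vec in self._freq[locus].items():
            if abs(vec[population_index] - 1.0) <= _DIAGNOSTIC_TOL:
                return allele
        raise ValueError(
            f"locus {locus!r} has no allele fixed in population "
            f"{self.populations[population_index]!r} (locus is not diagnostic)"
        )

    def subset(self, loci: Sequence[str]) -> "AlleleFrequencyTable":
        new = object.__new__(AlleleFrequencyTable)
        new.populations = self.populations
        new._freq = {l: self._freq[l] for l in loci}
        new.dominant_alleles = {
            l: a for l, a in self.dominant_alleles.items() if l in new._freq
        }
        return new


class CodominantGenotype:
    """One individual's codominant multilocus genotype.

    ``calls`` maps each locus to an unordered pair of allele identifiers, or
    to ``None`` for missing data.  Pair order carries no information.
    """

    def __init__(self, calls: Mapping[str, Optional[tuple[str, str]]]):
        self.calls: dict[str, Optional[tuple[str, str]]] = {}
        for locus, pair in calls.items():
            if pair is None:
                self.calls[str(locus)] = None
                continue
            a, b = pair
            self.calls[str(locus)] = (str(a), str(b))

    @property
    def loci(self) -> tuple[str, ...]:
        return tuple(self.calls)

    @property
    def n(self) -> int:
        """Number of non-missing loci."""
        return sum(pair is not None for pair in self.calls.values())

    def non_missing(self):
        return ((l, p) for l, p in self.calls.items() if p is not None)

    def subset(self, loci: Sequence[str]) -> "CodominantGenotype":
        return CodominantGenotype({l: self.calls[l] for l in loci})


class DominantPhenotype:
    """One individual's dominant-marker phenotype (band present/absent).

    ``bands`` maps each marker to 1 (band present), 0 (band absent) or
    ``None`` (missing).  ``dominant_alleles`` names the dominant allele at
    each marker; the remaining allele in the frequency table is recessive.
    """

    def __init__(
        self,
        bands: Mapping[str, Optional[int]],
        dominant_alleles: Mapping[str, str],
    ):
        self.bands: dict[str, Optional[int]] = {}
        for marker, state in bands.items():
            if state is not None and state not in (0, 1, False, True):
                raise ValueError(
                    f"band state at marker {marker!r} must be 0, 1 or missing; "
                    f"got {state!r}"
                )
            self.bands[str(marker)] = None if state is None else int(state)
        self.dominant_alleles = {str(k): str(v) for k, v in dominant_alleles.items()}
        for marker, state in self.bands.items():
            if state is not None and marker not in self.dominant_alleles:
                raise ValueError(
                    f"marker {marker!r} has no dominant allele assigned"
                )

    @property
    def loci(self) -> tuple[str, ...]:
        return tuple(self.bands)

    @property
    def n(self) -> int:
        return sum(state is not None for state in self.bands.values())

    def subset(self, loci: Sequence[str]) -> "DominantPhenotype":
        return DominantPhenotype(
            {l: self.bands[l] for l in loci},
            {l: self.dominant_alleles[l] for l in loci if l in self.dominant_alleles},
        )


# -- single-locus genotype probabilities --------------------------------------


def genotype_prob_codominant(
    freqs_at_locus: Mapping[str, Sequence[float]],
    observed_pair: tuple[str, str],
    theta: GenomicProportions,
) -> float:
    """Probability of an unordered allele pair at one locus for a hybrid
    with genomic proportions ``theta``, given two-population allele
    frequencies ``{allele: (f_pop1, f_pop2)}``.

    Homozygote (j, j):  p11*f_j1^2 + p12*f_j1*f_j2 + p22*f_j2^2.
    Heterozygote (j, k): p11*2*f_j1*f_k1 + p12*(f_j1*f_k2 + f_k1*f_j2)
                         + p22*2*f_j2*f_k2.
    """
    coef = _pair_coefficients(freqs_at_locus, observed_pair, locus="locus")
    return float(np.dot(coef, theta.as_array()))


def _pair_coefficients(
    freqs_at_locus: Mapping[str, Sequence[float]],
    observed_pair: tuple[str, str],
    locus: object,
) -> np.ndarray:
    """Mixture coefficients (on p11, p12, p22) of a single-locus genotype."""
    j, k = observed_pair
    try:
        fj = np.asarray(freqs_at_locus[j], dtype=float)
    except KeyError:
        raise UnknownAlleleError(locus, j) from None
    try:
        fk = np.asarray(freqs_at_locus[k], dtype=float)
    except KeyError:
        raise UnknownAlleleError(locus, k) from None
    if j == k:
        return np.array([fj[0] ** 2, fj[0] * fj[1], fj[1] ** 2])
    return np.array(
        [
            2.0 * fj[0] * fk[0],
            fj[0] * fk[1] + fk[0] * fj[1],
            2.0 * fj[1] * fk[1],
        ]
    )


def genotype_prob_generalA(
    freqs_at_locus: Mapping[str, Sequence[float]],
    observed_pair: tuple[str, str],
    pairwise_proportions: Mapping[tuple[int, int], float],
) -> float:
    """Single-locus genotype probability with A >= 2 ancestral gene pools.

    ``pairwise_proportions`` maps (a, b) with 1-based population indices,
    a <= b, to the proportion of loci with one allele copy from pool a and
    one from pool b; the proportions must be nonnegative and sum to 1.
    For A=2 this reduces exactly to :func:`genotype_prob_codominant` with
    theta = (p_(1,1), p_(1,2), p_(2,2)).
    """
    props: dict[tuple[int, int], float] = {}
    for (a, b), p in pairwise_proportions.items():
        key = (min(a, b), max(a, b))
        props[key] = props.get(key, 0.0) + float(p)
    if any(p < -_SIMPLEX_TOL for p in props.values()):
        raise ValueError("pairwise genomic proportions must be nonnegative")
    total = sum(props.values())
    if abs(total - 1.0) > _SIMPLEX_TOL:
        raise ValueError(
            f"pairwise genomic proportions sum to {total!r}, expected 1"
        )
    j, k = observed_pair
    try:
        fj = np.asarray(freqs_at_locus[j], dtype=float)
    except KeyError:
        raise UnknownAlleleError("locus", j) from None
    try:
        fk = np.asarray(freqs_at_locus[k], dtype=float)
    except KeyError:
        raise UnknownAlleleError("locus", k) from None
    prob = 0.0
    for (a, b), p in props.items():
        ia, ib = a - 1, b - 1
        if j == k:
            if a == b:
                prob += p * fj[ia] ** 2
            else:
                prob += p * fj[ia] * fj[ib]
        else:
            if a == b:
                prob += p * 2.0 * fj[ia] * fk[ia]
            else:
                prob += p * (fj[ia] * fk[ib] + fk[ia] * fj[ib])
    return float(prob)


# -- multilocus log-likelihoods ------------------------------------------------


def codominant_coefficients(
    genotype: CodominantGenotype, freqs: AlleleFrequencyTable
) -> tuple[np.ndarray, list[str]]:
    """Per-locus mixture coefficients: row i dotted with (p11, p12, p22)
    gives the probability of the genotype at non-missing locus i."""
    if freqs.n_populations != 2:
        raise ValueError(
            "genomic-proportions likelihoods require a two-population table; "
            "use genotype_prob_generalA for A > 2"
        )
    rows, loci = [], []
    for locus, pair in genotype.non_missing():
        rows.append(_pair_coefficients(freqs.frequencies(locus), pair, locus))
        loci.append(locus)
    if not rows:
        raise ValueError("genotype has no non-missing loci")
    return np.array(rows), loci


def dominant_coefficients(
    phenotype: DominantPhenotype, freqs: AlleleFrequencyTable
) -> tuple[np.ndarray, list[str]]:
    """Per-marker mixture coefficients for dominant (band) phenotypes.

    Band absent contributes Pr(recessive homozygote); band present is its
    complement (which is Pr(j,j) + Pr(j,k) for a biallelic marker).
    """
    if freqs.n_populations != 2:
        raise ValueError("dominant likelihoods require a two-population table")
    rows, loci = [], []
    for marker, state in phenotype.bands.items():
        if state is None:
            continue
        alleles = freqs.alleles(marker)
        if len(alleles) != 2:
            raise ValueError(
                f"dominant marker {marker!r} must be biallelic in the "
                f"frequency table; found alleles {alleles!r}"
            )
        dom = phenotype.dominant_alleles[marker]
        if dom not in alleles:
            raise UnknownAlleleError(marker, dom)
        rec = alleles[0] if alleles[1] == dom else alleles[1]
        fk = freqs.lookup(marker, rec)
        absent = np.array([fk[0] ** 2, fk[0] * fk[1], fk[1] ** 2])
        rows.append(1.0 - absent if state == 1 else absent)
        loci.append(marker)
    if not rows:
        raise ValueError("phenotype has no non-missing markers")
    return np.array(rows), loci


def loglik_from_coefficients(coef: np.ndarray, thetas: np.ndarray) -> np.ndarray:
    """Log-likelihood(s) from a per-locus coefficient matrix.

    ``thetas`` may be a single point (3,) or a stack (K, 3).  Any point at
    which some locus has probability <= 0 evaluates to LOG_IMPOSSIBLE.
    """
    thetas = np.asarray(thetas, dtype=float)
    single = thetas.ndim == 1
    t = thetas[None, :] if single else thetas
    probs = coef @ t.T  # (n_loci, K)
    ok = (probs > 0.0).all(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lls = np.where(ok, np.log(np.where(probs > 0, probs, 1.0)).sum(axis=0),
                       LOG_IMPOSSIBLE)
    return float(lls[0]) if single else lls


def loglik_codominant(
    genotype: CodominantGenotype,
    freqs: AlleleFrequencyTable,
    theta: GenomicProportions,
) -> float:
    """Joint log-likelihood of genomic proportions for a codominant
    genotype: the sum over non-missing loci of the log genotype
    probabilities.  Missing loci contribute nothing; if any locus is
    impossible under ``theta`` the sentinel ``LOG_IMPOSSIBLE`` is returned.
    """
    coef, _ = codominant_coefficients(genotype, freqs)
    return float(loglik_from_coefficients(coef, theta.as_array()))


def loglik_dominant(
    phenotype: DominantPhenotype,
    freqs: AlleleFrequencyTable,
    theta: GenomicProportions,
) -> float:
    """Joint log-likelihood for dominant markers: band-present markers
    contribute ln(Pr(j,j) + Pr(j,k)), band-absent ln(Pr(k,k))."""
    coef, _ = dominant_coefficients(phenotype, freqs)
    return float(loglik_from_coefficients(coef, theta.as_array()))


def impossible_loci(
    genotype: CodominantGenotype,
    freqs: AlleleFrequencyTable,
    theta: GenomicProportions,
    dominant: bool = False,
) -> list[str]:
    """Loci whose observed state has probability 0 under ``theta``."""
    if dominant:
        coef, loci = dominant_coefficients(genotype, freqs)  # type: ignore[arg-type]
    else:
        coef, loci = codominant_coefficients(genotype, freqs)
    probs = coef @ theta.as_array()
    return [l for l, p in zip(loci, probs) if p <= 0.0]


# -- closed-form MLE for diagnostic markers ------------------------------------


def closed_form_mle_diagnostic(
    genotype: CodominantGenotype, freqs: AlleleFrequencyTable
) -> HybridIndices:
    """Exact joint MLE when every scored locus is diagnostic.

    With diagnostic markers each allele copy's ancestry is read directly, so
    the likelihood is multinomial in the observed locus fractions and is
    maximized at S_hat = x22 + x12/2 and H_I_hat = x12, where x22 and x12
    are the fractions of loci homozygous for population-2 alleles and
    heterozygous for alleles from the two populations.
    """
    counts = Counter()
    n = 0
    for locus, pair in genotype.non_missing():
        if not freqs.is_diagnostic(locus):
            raise ValueError(
                f"locus {locus!r} is not diagnostic; the closed-form MLE "
                "applies only to diagnostic markers -- use the MCMC estimator"
            )
        src = tuple(
            sorted(
                1 if abs(freqs.lookup(locus, a)[0] - 1.0) <= _DIAGNOSTIC_TOL else 2
                for a in pair
            )
        )
        counts[src] += 1
        n += 1
    if n == 0:
        raise ValueError("genotype has no non-missing loci")
    n12 = counts[(1, 2)]
    n22 = counts[(2, 2)]
    return HybridIndices(S=(n22 + 0.5 * n12) / n, H_I=n12 / n)
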