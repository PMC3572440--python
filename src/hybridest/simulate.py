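"""Forward simulation of admixed populations and controlled crosses.

Individuals are diploid; every allele copy carries a tag naming the
ancestral population (1 or 2) it descends from, so the true ancestry index
S (fraction of tags equal to 2) and true interclass heterozygosity H_I
(fraction of loci with mixed tags) are read off each genome exactly.  At
non-diagnostic loci a concrete allele identifier is drawn from the source
population's frequency distribution at founding (and for immigrants), and
inherited thereafter; the observable genotype is the pair of allele
identifiers, while the tags remain hidden truth.

Two admixture models are provided: closed *intermixture* (a founding
mixture followed by random mating and drift) and the *continent-island*
model (the same, with each offspring replaced by a pure parental immigrant
with probability m per generation).  Controlled crosses (F1, F2,
backcrosses, Fk up to F10) can be simulated with free recombination or on
a structured genome of four chromosomes with one obligate crossover per
arm per meiosis.
"""

from __future__ import annotations

import dataclasses
import re
from collections.abc import Sequence
from typing import Optional

import numpy as np

from .likelihood import AlleleFrequencyTable, CodominantGenotype, DominantPhenotype, HybridIndices

__all__ = [
    "GenomeModel",
    "SimulationConfig",
    "SimulatedIndividual",
    "SimulationRun",
    "simulate_intermixture",
    "simulate_continent_island",
    "simulate_cross",
    "meiosis_linked",
    "sample_markers",
    "true_indices",
]


@dataclasses.dataclass(frozen=True)
class GenomeModel:
    """Structured genome: chromosomes of two arms with evenly spaced loci.

    The default models four 200 cM chromosomes of 100 loci each (two arms
    of 50 loci, adjacent loci 2 cM apart) with exactly one crossover per
    arm per meiosis, placed uniformly on the arm's inter-locus intervals.
    """

    chromosomes: int = 4
    arms_per_chromosome: int = 2
    loci_per_arm: int = 50
    spacing_cm: float = 2.0

    def __post_init__(self):
        if min(self.chromosomes, self.arms_per_chromosome) < 1 or self.loci_per_arm < 2:
            raise ValueError("invalid genome dimensions")
        if self.spacing_cm <= 0:
            raise ValueError("spacing_cm must be > 0")

    @property
    def n_arms(self) -> int:
        return self.chromosomes * self.arms_per_chromosome

    @property
    def n_loci(self) -> int:
        return self.n_arms * self.loci_per_arm

    def locus_names(self) -> list[str]:
        return [f"L{i + 1:03d}" for i in range(self.n_loci)]


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Admixture-simulation settings.

    ``mu`` is the founding fraction drawn from parental population 1;
    ``m`` is the per-individual probability per generation of being
    replaced by a pure parental immigrant (0 = closed intermixture).
    ``loci`` is either a count of diagnostic markers or a two-population
    AlleleFrequencyTable from which founder alleles are drawn.
    """

    N: int
    mu: float = 0.5
    m: float = 0.0
    generations: int = 1
    loci: int | AlleleFrequencyTable = 65
    seed: int = 0

    def __post_init__(self):
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError("mu must be in [0, 1]")
        if not (0.0 <= self.m <= 1.0):
            raise ValueError("m must be in [0, 1]")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")

    def frequency_table(self) -> AlleleFrequencyTable:
        if isinstance(self.loci, AlleleFrequencyTable):
            if self.loci.n_populations != 2:
                raise ValueError("simulation requires a two-population table")
            return self.loci
        return AlleleFrequencyTable.diagnostic(int(self.loci))


class SimulatedIndividual:
    """Ancestry-tagged diploid genome.

    ``tags`` is an (L, 2) array of source populations in {1, 2};
    ``alleles`` is an (L, 2) array of indices into the frequency table's
    allele register per locus.
    """

    __slots__ = ("tags", "alleles", "loci", "_allele_names")

    def __init__(
        self,
        tags: np.ndarray,
        alleles: np.ndarray,
        loci: tuple[str, ...],
        allele_names: list[tuple[str, ...]],
    ):
        self.tags = tags
        self.alleles = alleles
        self.loci = loci
        self._allele_names = allele_names

    def true_indices(self, subset: Optional[Sequence[int]] = None) -> HybridIndices:
        tags = self.tags if subset is None else self.tags[np.asarray(subset)]
        s = float(np.mean(tags == 2))
        h = float(np.mean(tags[:, 0] != tags[:, 1]))
        return HybridIndices(S=s, H_I=h)

    def to_genotype(self, subset: Optional[Sequence[int]] = None) -> CodominantGenotype:
        idx = range(len(self.loci)) if subset is None else subset
        calls = {}
        for i in idx:
            names = self._allele_names[i]
            a, b = self.alleles[i]
            calls[self.loci[i]] = (names[a], names[b])
        return CodominantGenotype(calls)

    def to_dominant(
        self,
        dominant_alleles: dict[str, str],
        subset: Optional[Sequence[int]] = None,
    ) -> DominantPhenotype:
        """Collapse the codominant genotype to band presence/absence."""
        idx = range(len(self.loci)) if subset is None else subset
        bands = {}
        doms = {}
        for i in idx:
            locus = self.loci[i]
            names = self._allele_names[i]
            dom = dominant_alleles[locus]
            pair = (names[self.alleles[i, 0]], names[self.alleles[i, 1]])
            bands[locus] = int(dom in pair)
            doms[locus] = dom
        return DominantPhenotype(bands, doms)


def true_indices(
    individual: SimulatedIndividual, subset: Optional[Sequence[int]] = None
) -> HybridIndices:
    """Exact tag-based (S, H_I), optionally restricted to a marker subset."""
    return individual.true_indices(subset)


@dataclasses.dataclass
class SimulationRun:
    """Per-generation output of an admixture simulation.

    ``generations[g]`` holds generation g's individuals; for the
    continent-island model these are the offspring *before* immigrant
    replacement, while ``post_dispersal[g]`` (when present) holds the
    population that actually breeds the next generation.  ``immigrants``
    counts replacements per generation (index 0 is the founding
    generation, which receives none).
    """

    generations: list[list[SimulatedIndividual]]
    freqs: AlleleFrequencyTable
    config: SimulationConfig
    post_dispersal: Optional[list[list[SimulatedIndividual]]] = None
    immigrants: Optional[list[int]] = None


# -- array-level machinery -----------------------------------------------------


def _wrap(tags, alleles, loci, allele_names) -> list[SimulatedIndividual]:
    return [
        SimulatedIndividual(tags[i], alleles[i], loci, allele_names)
        for i in range(tags.shape[0])
    ]


def _allele_probs(freqs: AlleleFrequencyTable):
    """Per-locus allele-name register and per-population sampling weights."""
    names = [freqs.alleles(l) for l in freqs.loci]
    probs = [
        np.array([freqs.lookup(l, a) for a in freqs.alleles(l)]).T  # (2, n_alleles)
        for l in freqs.loci
    ]
    return names, probs


def _draw_pure(n: int, population: int, probs, rng) -> tuple[np.ndarray, np.ndarray]:
    """n pure individuals of the given population: tags constant, alleles
    drawn locus-by-locus from that population's frequencies."""
    L = len(probs)
    tags = np.full((n, L, 2), population, dtype=np.int8)
    alleles = np.empty((n, L, 2), dtype=np.int16)
    for i, p in enumerate(probs):
        w = p[population - 1]
        w = w / w.sum()
        alleles[:, i, :] = rng.choice(len(w), size=(n, 2), p=w)
    return tags, alleles


def _linked_homolog_choice(genome: GenomeModel, n: int, rng) -> np.ndarray:
    """(n, L) homolog index per gamete under the structured-genome model:
    per arm an independent starting homolog and exactly one breakpoint at a
    uniformly chosen inter-locus interval."""
    k = genome.loci_per_arm
    j = np.arange(k)
    cols = []
    for _ in range(genome.n_arms):
        start = rng.integers(0, 2, size=n)
        bp = rng.integers(0, k - 1, size=n)  # switch after locus index bp
        sel = start[:, None] ^ (j[None, :] > bp[:, None])
        cols.append(sel)
    return np.concatenate(cols, axis=1).astype(np.intp)


def _gametes(
    tags: np.ndarray,
    alleles: np.ndarray,
    parent_idx: np.ndarray,
    rng,
    genome: Optional[GenomeModel] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One gamete per entry of parent_idx: (n, L) tag and allele arrays."""
    n = len(parent_idx)
    L = tags.shape[1]
    if genome is None:
        pick = rng.integers(0, 2, size=(n, L))
    else:
        if genome.n_loci != L:
            raise ValueError("genome model does not match locus count")
        pick = _linked_homolog_choice(genome, n, rng)
    rows = np.asarray(parent_idx)[:, None]
    cols = np.arange(L)[None, :]
    return tags[rows, cols, pick], alleles[rows, cols, pick]


def meiosis_linked(
    parent: SimulatedIndividual, genome: GenomeModel, rng
) -> tuple[np.ndarray, np.ndarray]:
    """A single gamete from ``parent`` under the structured-genome model.

    Returns the gamete's (L,) tag and allele arrays.  ``rng`` is a
    numpy Generator (or a seed accepted by ``default_rng``).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    tags = parent.tags[None, ...]
    alleles = parent.alleles[None, ...]
    gt, ga = _gametes(tags, alleles, np.zeros(1, dtype=int), rng, genome)
    return gt[0], ga[0]


# -- admixture models ----------------------------------------------------------


def _run_admixture(config: SimulationConfig, keep_post: bool) -> SimulationRun:
    freqs = config.frequency_table()
    loci = freqs.loci
    allele_names, probs = _allele_probs(freqs)
    ss = np.random.SeedSequence(config.seed)
    rng_found, rng_mating, rng_meiosis, rng_imm = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    n1 = round(config.mu * config.N)
    t1, a1 = _draw_pure(n1, 1, probs, rng_found)
    t2, a2 = _draw_pure(config.N - n1, 2, probs, rng_found)
    tags = np.concatenate([t1, t2])
    alleles = np.concatenate([a1, a2])

    generations = [_wrap(tags, alleles, loci, allele_names)]
    post = [generations[0]] if keep_post else None
    immigrants = [0]

    for _ in range(config.generations):
        mothers = rng_mating.integers(0, config.N, size=config.N)
        fathers = rng_mating.integers(0, config.N, size=config.N)
        gt1, ga1 = _gametes(tags, alleles, mothers, rng_meiosis)
        gt2, ga2 = _gametes(tags, alleles, fathers, rng_meiosis)
        tags = np.stack([gt1, gt2], axis=2)
        alleles = np.stack([ga1, ga2], axis=2)
        generations.append(_wrap(tags.copy(), alleles.copy(), loci, allele_names))

        n_imm = 0
        if config.m > 0.0:
            replace = rng_imm.random(config.N) < config.m
            n_imm = int(replace.sum())
            if n_imm:
                pops = rng_imm.integers(1, 3, size=n_imm)
                for pop in (1, 2):
                    take = np.flatnonzero(replace)[pops == pop]
                    if take.size:
                        ti, ai = _draw_pure(take.size, pop, probs, rng_imm)
                        tags[take] = ti
                        alleles[take] = ai
        immigrants.append(n_imm)
        if keep_post:
            post.append(_wrap(tags.copy(), alleles.copy(), loci, allele_names))

    return SimulationRun(
        generations=generations,
        freqs=freqs,
        config=config,
        post_dispersal=post,
        immigrants=immigrants,
    )


def simulate_intermixture(config: SimulationConfig) -> SimulationRun:
    """Closed admixture: a founding mixture (fraction ``mu`` pure P1) then
    ``generations`` rounds of random mating (pairs drawn with replacement,
    selfing allowed) with unlinked loci.  Generation 0 is the founders."""
    if config.m != 0.0:
        raise ValueError("intermixture requires m=0; use simulate_continent_island")
    return _run_admixture(config, keep_post=False)


def simulate_continent_island(
    config: SimulationConfig, keep_post_dispersal: bool = True
) -> SimulationRun:
    """Admixture with recurrent immigration: after each generation's
    offspring are formed, each is independently replaced by a pure parental
    (P1 or P2 with probability 1/2 each) with probability ``m``.  Reported
    generations are the offspring before replacement; the post-replacement
    populations (which breed next) are kept in ``post_dispersal``.  With
    ``m=0`` the run is identical to :func:`simulate_intermixture` under the
    same seed."""
    return _run_admixture(config, keep_post=keep_post_dispersal)


# -- controlled crosses --------------------------------------------------------

_CROSS_RE = re.compile(r"^F([0-9]+)$")


def simulate_cross(
    cross: str,
    genome: Optional[GenomeModel] = None,
    n_loci: Optional[int] = None,
    n_individuals: int = 100,
    seed: int = 0,
    pool_size: Optional[int] = None,
) -> list[SimulatedIndividual]:
    """Simulate a controlled cross from parental lines with diagnostic
    alleles at every marker.

    ``cross`` is one of F1, F2, B1, B2 or Fk for 3 <= k <= 10.  With a
    :class:`GenomeModel` gametes are produced by the one-crossover-per-arm
    meiosis; otherwise ``n_loci`` unlinked markers are used.  Later
    generations (Fk, k >= 3) are produced by random mating within a pool of
    ``pool_size`` (default ``n_individuals``) individuals per generation.
    """
    if genome is not None:
        L = genome.n_loci
        loci = tuple(genome.locus_names())
    else:
        if n_loci is None:
            raise ValueError("provide either a GenomeModel or n_loci")
        L = int(n_loci)
        loci = tuple(f"L{i + 1:03d}" for i in range(L))
    if L < 1:
        raise ValueError("at least one locus is required")
    allele_names = [("1", "2")] * L
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    def wrap(tags):
        return _wrap(tags, (tags - 1).astype(np.int16), loci, allele_names)

    def pure(pop, n):
        return np.full((n, L, 2), pop, dtype=np.int8)

    def f1(n):
        out = np.empty((n, L, 2), dtype=np.int8)
        out[:, :, 0] = 1
        out[:, :, 1] = 2
        return out

    def offspring(tags_a, idx_a, tags_b, idx_b):
        ta = tags_a.astype(np.int8)
        ga1, _ = _gametes(ta, ta, idx_a, rng, genome)
        tb = tags_b.astype(np.int8)
        ga2, _ = _gametes(tb, tb, idx_b, rng, genome)
        return np.stack([ga1, ga2], axis=2)

    n = int(n_individuals)
    if cross == "F1":
        return wrap(f1(n))
    if cross == "B1":
        sires = f1(n)
        dams = pure(1, n)
        return wrap(offspring(sires, np.arange(n), dams, np.arange(n)))
    if cross == "B2":
        sires = f1(n)
        dams = pure(2, n)
        return wrap(offspring(sires, np.arange(n), dams, np.arange(n)))
    match = _CROSS_RE.match(cross)
    if not match:
        raise ValueError(f"unknown cross label {cross!r}")
    k = int(match.group(1))
    if not 2 <= k <= 10:
        raise ValueError(f"cross {cross!r} unsupported; use F1..F10, B1 or B2")
    pool_n = int(pool_size or n)
    pool = f1(max(pool_n, 2))
    for gen in range(2, k + 1):
        size = n if gen == k else max(pool_n, 2)
        mothers = rng.integers(0, pool.shape[0], size=size)
        fathers = rng.integers(0, pool.shape[0], size=size)
        pool = offspring(pool, mothers, pool, fathers)
    return wrap(pool)


# -- marker sampling -----------------------------------------------------------

_REGIME_RE = re.compile(r"^systematic-([0-9.]+)cM$")


def sample_markers(
    genome: GenomeModel | int,
    L: int,
    regime: str = "random",
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Choose ``L`` marker indices under a sampling regime.

    ``random`` draws a simple random sample without replacement.
    ``systematic-<x>cM`` walks the genome at x-cM intervals from a single
    random starting locus, wrapping across chromosomes in register order
    (requires a :class:`GenomeModel` with spacing dividing x).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = genome.n_loci if isinstance(genome, GenomeModel) else int(genome)
    if L < 1 or L > n:
        raise ValueError(f"L={L} out of range for a genome of {n} loci")
    if regime == "random":
        return np.sort(rng.choice(n, size=L, replace=False))
    match = _REGIME_RE.match(regime)
    if not match:
        raise ValueError(f"unknown sampling regime {regime!r}")
    if not isinstance(genome, GenomeModel):
        raise ValueError("systematic regimes require a GenomeModel")
    interval = float(match.group(1))
    step = interval / genome.spacing_cm
    if abs(step - round(step)) > 1e-9 or round(step) < 1:
        raise ValueError(
            f"interval {interval} cM is not a positive multiple of the "
            f"{genome.spacing_cm} cM locus spacing"
        )
    step = int(round(step))
    start = int(rng.integers(0, n))
    idx = (start + np.arange(L) * step) % n
    if len(np.unique(idx)) < L:
        raise ValueError(
            f"L={L} at {interval} cM intervals revisits loci on a "
            f"{n}-locus genome; reduce L or widen the interval"
        )
    return idx
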