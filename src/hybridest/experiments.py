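"""In-silico experiments: marker subsampling, frequency misspecification,
and linkage/sampling-regime bias-variance.

Each experiment is a pure function of its inputs and a seed, returning a
long-format table of per-individual measurements (an
:class:`ExperimentResult`).  Rates and summaries (medians, interquartile
ranges, means, variances) are recomputed from the raw rows on demand and
never stored redundantly.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence
from typing import Optional

import numpy as np
import pandas as pd

from .likelihood import (
    AlleleFrequencyTable,
    CodominantGenotype,
    closed_form_mle_diagnostic,
)
from .estimation import McmcConfig, estimate_sample
from .classification import CRITERIA, HYBRID_CLASSES, _decide, class_loglikelihoods, classify
from .simulate import (
    GenomeModel,
    SimulatedIndividual,
    SimulationConfig,
    sample_markers,
    simulate_cross,
    simulate_intermixture,
)

__all__ = [
    "ExperimentResult",
    "default_swarm",
    "subsample_false_classification",
    "misspecification_experiment",
    "linkage_bias_variance",
    "MISSPEC_SCENARIOS",
]

#: Seed of the packaged synthetic hybrid swarm.  Fixed so that the default
#: experiment input is reproducible across sessions.
DEFAULT_SWARM_SEED = 1729


@dataclasses.dataclass
class ExperimentResult:
    """Long-format experiment table: one row per (condition, replicate,
    individual, statistic)."""

    data: pd.DataFrame

    def summarize(self, by: Sequence[str]) -> pd.DataFrame:
        """Median, interquartile range, mean and variance of ``value``
        grouped by the given condition columns plus ``statistic``."""
        grouped = self.data.groupby([*by, "statistic"])["value"]
        out = grouped.agg(
            median="median",
            q25=lambda v: v.quantile(0.25),
            q75=lambda v: v.quantile(0.75),
            mean="mean",
            var="var",
            n="count",
        )
        return out.reset_index()


def default_swarm(
    seed: int = DEFAULT_SWARM_SEED,
) -> tuple[list[SimulatedIndividual], AlleleFrequencyTable]:
    """The packaged synthetic hybrid swarm: closed intermixture of N=100
    diploids founded half-and-half, run for 20 generations, scored at 65
    diagnostic codominant markers.  After 20 generations the population is
    an old swarm -- no true parentals, F1s or first backcrosses remain --
    so *any* confident six-class assignment of these individuals is a
    false positive."""
    config = SimulationConfig(N=100, mu=0.5, m=0.0, generations=20, loci=65, seed=seed)
    run = simulate_intermixture(config)
    return run.generations[-1], run.freqs


# -- marker subsampling and false classification -------------------------------


def _diagnostic_category_matrix(
    genotypes: Sequence[CodominantGenotype], freqs: AlleleFrequencyTable
) -> np.ndarray:
    """(n_individuals, n_loci) matrix of locus categories for diagnostic
    markers: 0 = homozygous population-1, 1 = interclass heterozygous,
    2 = homozygous population-2."""
    loci = freqs.loci
    pop2 = {l: freqs.population_allele(l, 1) for l in loci}
    cats = np.empty((len(genotypes), len(loci)), dtype=np.int8)
    for i, g in enumerate(genotypes):
        for j, l in enumerate(loci):
            pair = g.calls[l]
            if pair is None:
                raise ValueError("subsampling requires complete genotypes")
            cats[i, j] = (pair[0] == pop2[l]) + (pair[1] == pop2[l])
    return cats


# per-category log-probabilities under the six class points; at diagnostic
# loci Pr(hom1, het, hom2) = (p11, p12, p22).
_CLASS_LOGP = {
    name: np.log(np.clip(theta.as_array(), 1e-320, None))
    for name, theta in HYBRID_CLASSES.items()
}


def _decisions_from_counts(
    counts: np.ndarray, criterion: str
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized classification of diagnostic-marker count vectors.

    ``counts`` is (n, 3): per-individual counts of (hom-pop1, het,
    hom-pop2) loci.  Returns (classified, best_class_index) arrays; the
    class order is that of HYBRID_CLASSES.  Exactly reproduces
    :func:`hybridest.classification.classify` for all-diagnostic markers,
    where the continuous maximum is the closed-form multinomial value.
    """
    n = counts.sum(axis=1, keepdims=True)
    logp = np.stack([_CLASS_LOGP[c] for c in HYBRID_CLASSES])  # (6, 3)
    class_ll = counts @ logp.T  # (n_ind, 6)
    impossible = (counts[:, None, :] * (logp[None, :, :] < -700)).any(axis=2)
    class_ll = np.where(impossible, -1e308, class_ll)
    order = np.argsort(-class_ll, axis=1)
    best = order[:, 0]
    rows = np.arange(len(counts))
    gap = class_ll[rows, best] - class_ll[rows, order[:, 1]]
    frac = counts / n
    with np.errstate(divide="ignore", invalid="ignore"):
        mle_ll = np.where(counts > 0, counts * np.log(np.where(frac > 0, frac, 1.0)), 0.0).sum(axis=1)
    aic_ok = class_ll[rows, best] >= mle_ll - 1.0 - 1e-9
    distinct = gap > 2.0
    if criterion == "classes-only":
        classified = distinct
    elif criterion == "AIC-only":
        classified = aic_ok
    elif criterion == "strict-2LL-and-AIC":
        classified = distinct & aic_ok
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return classified, best


def subsample_false_classification(
    genotypes: Sequence[CodominantGenotype | SimulatedIndividual],
    freqs: AlleleFrequencyTable,
    L_values: Sequence[int],
    reps: int = 200,
    criteria: Sequence[str] = CRITERIA,
    seed: int = 0,
    mcmc_config: Optional[McmcConfig] = None,
) -> ExperimentResult:
    """Repeatedly subsample ``L`` markers without replacement and re-run the
    six-class test on every individual under each criterion.

    Rows record, per individual, whether a confident classification was
    reached (``classified``), and whether it specifically named F1
    (``classified_f1``) or a parental class (``classified_parental``).  On
    a later-generation swarm every 1 in the ``classified`` column is a
    false positive.  For diagnostic marker tables the per-subset
    classification is computed from the exact closed-form maximum
    (identical to the sampler's result); otherwise each subset is
    classified through :func:`hybridest.classification.classify`.
    """
    genos = [
        g.to_genotype() if isinstance(g, SimulatedIndividual) else g for g in genotypes
    ]
    loci = list(freqs.loci)
    for L in L_values:
        if L > len(loci):
            raise ValueError(f"L={L} exceeds the {len(loci)} available markers")
    for crit in criteria:
        if crit not in CRITERIA:
            raise ValueError(f"unknown criterion {crit!r}")
    class_names = list(HYBRID_CLASSES)
    diagnostic = freqs.all_diagnostic()
    cats = _diagnostic_category_matrix(genos, freqs) if diagnostic else None

    records = []
    for L in L_values:
        for rep in range(reps):
            rng = np.random.default_rng(np.random.SeedSequence([seed, L, rep]))
            subset_idx = rng.choice(len(loci), size=L, replace=False)
            if diagnostic:
                sub = cats[:, subset_idx]
                counts = np.stack([(sub == c).sum(axis=1) for c in (0, 1, 2)], axis=1)
                for crit in criteria:
                    classified, best = _decisions_from_counts(counts, crit)
                    for i in range(len(genos)):
                        name = class_names[best[i]]
                        records.append(
                            (L, crit, rep, i, int(classified[i]),
                             int(classified[i] and name == "F1"),
                             int(classified[i] and name in ("P1", "P2")))
                        )
            else:
                subset = [loci[j] for j in subset_idx]
                sub_freqs = freqs.subset(subset)
                for i, g in enumerate(genos):
                    gsub = g.subset(subset)
                    for crit in criteria:
                        res = classify(
                            gsub, sub_freqs, config=mcmc_config, criterion=crit
                        )
                        hit = res.decision.startswith("classified-as-")
                        records.append(
                            (L, crit, rep, i, int(hit),
                             int(hit and res.best_class == "F1"),
                             int(hit and res.best_class in ("P1", "P2")))
                        )
    df = pd.DataFrame.from_records(
        records,
        columns=["L", "criterion", "replicate", "individual",
                 "classified", "classified_f1", "classified_parental"],
    )
    long = df.melt(
        id_vars=["L", "criterion", "replicate", "individual"],
        value_vars=["classified", "classified_f1", "classified_parental"],
        var_name="statistic",
        value_name="value",
    )
    return ExperimentResult(long)


def classification_rates(result: ExperimentResult) -> pd.DataFrame:
    """Per (L, criterion, replicate) fractions, recomputed from raw rows."""
    df = result.data
    rates = (
        df.groupby(["L", "criterion", "replicate", "statistic"])["value"]
        .mean()
        .rename("rate")
        .reset_index()
    )
    return rates


# -- parental-frequency misspecification ---------------------------------------

MISSPEC_SCENARIOS = (
    "diagnostic",
    "0.9/0.1",
    "0.8/0.2",
    "0.7/0.3",
    "mixed-25+25",
    "mixed-with-2-diagnostic",
)


def _scenario_table(scenario: str, L: int) -> AlleleFrequencyTable:
    """Allele-frequency table for a named misspecification scenario.

    Allele ``A`` is the population-1-typical allele at every locus, so any
    genotype simulated under one scenario can be scored under another.
    """
    loci = [f"M{i + 1:03d}" for i in range(L)]
    if scenario == "diagnostic":
        f1 = np.ones(L)
    elif scenario in ("0.9/0.1", "0.8/0.2", "0.7/0.3"):
        f1 = np.full(L, float(scenario.split("/")[0]))
    elif scenario in ("mixed-25+25", "mixed-with-2-diagnostic"):
        if L != 50:
            raise ValueError(f"scenario {scenario!r} is defined for L=50 markers")
        f1 = np.concatenate([np.full(25, 0.9), np.full(25, 0.7)])
        if scenario == "mixed-with-2-diagnostic":
            f1[0] = 1.0
            f1[25] = 1.0
    else:
        raise ValueError(
            f"unknown scenario {scenario!r}; choose from {MISSPEC_SCENARIOS}"
        )
    return AlleleFrequencyTable.biallelic(loci, f1, 1.0 - f1)


def _assumed_table(actual: str, assumed: str, L: int) -> AlleleFrequencyTable:
    if assumed == "mixed-with-2-diagnostic":
        # two loci known diagnostic, the remaining 48 assumed 0.8/0.2
        if L != 50:
            raise ValueError("scenario 'mixed-with-2-diagnostic' requires L=50")
        f1 = np.full(50, 0.8)
        f1[0] = 1.0
        f1[25] = 1.0
        loci = [f"M{i + 1:03d}" for i in range(50)]
        return AlleleFrequencyTable.biallelic(loci, f1, 1.0 - f1)
    return _scenario_table(assumed, L)


def misspecification_experiment(
    actual_scenario: str,
    assumed_scenario: str,
    N: int = 50,
    generations: int = 10,
    L: int = 50,
    seed: int = 0,
    n_controls: int = 100,
    mcmc_config: Optional[McmcConfig] = None,
) -> ExperimentResult:
    """Simulate admixture under one set of parental allele frequencies and
    estimate (S, H_I) under another.

    A small population (default N=50) is founded half-and-half and run for
    ``generations`` rounds of random mating under the *actual* scenario's
    frequencies; every final-generation individual, plus ``n_controls``
    pure parentals of each population drawn from the actual frequencies,
    is then estimated under the *assumed* scenario's table.  Rows report
    the estimates, the tag-based truths and their differences.
    """
    actual = _scenario_table(actual_scenario, L)
    assumed = _assumed_table(actual_scenario, assumed_scenario, L)
    ss = np.random.SeedSequence([seed, 7])
    sim_seed, ctrl_seed, est_seed = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3))

    run = simulate_intermixture(
        SimulationConfig(
            N=N, mu=0.5, m=0.0, generations=generations, loci=actual, seed=sim_seed
        )
    )
    admixed = run.generations[-1]

    from .simulate import _allele_probs, _draw_pure, _wrap  # array-level helpers

    allele_names, probs = _allele_probs(actual)
    rng = np.random.default_rng(ctrl_seed)
    controls = {}
    for pop in (1, 2):
        t, a = _draw_pure(n_controls, pop, probs, rng)
        controls[f"control-P{pop}"] = _wrap(t, a, actual.loci, allele_names)

    groups = {"admixed": admixed, **controls}
    groups = {k: v for k, v in groups.items() if v}
    config = mcmc_config or McmcConfig(steps=200)
    records = []
    for group, individuals in groups.items():
        genos = {str(i): ind.to_genotype() for i, ind in enumerate(individuals)}
        if assumed.all_diagnostic():
            est = []
            for g in genos.values():
                idx = closed_form_mle_diagnostic(g, assumed)
                est.append((idx.S, idx.H_I))
        else:
            cfg = dataclasses.replace(config, seed=est_seed)
            table = estimate_sample(genos, assumed, cfg)
            est = list(zip(table["S_pop2"], table["H_I"]))
        for i, (ind, (s_hat, h_hat)) in enumerate(zip(individuals, est)):
            truth = ind.true_indices()
            for stat, value in (
                ("S_hat", s_hat),
                ("H_hat", h_hat),
                ("S_true", truth.S),
                ("H_true", truth.H_I),
                ("S_err", s_hat - truth.S),
                ("H_err", h_hat - truth.H_I),
            ):
                records.append(
                    (actual_scenario, assumed_scenario, L, group, 0, i, stat, value)
                )
    df = pd.DataFrame.from_records(
        records,
        columns=["actual", "assumed", "L", "group", "replicate", "individual",
                 "statistic", "value"],
    )
    return ExperimentResult(df)


# -- linkage and sampling-regime bias/variance ---------------------------------


def linkage_bias_variance(
    cross_types: Sequence[str] = ("F2", "B1", "F10"),
    L_values: Sequence[int] = (3, 10, 20, 30, 40, 50, 60),
    regimes: Sequence[str] = ("random", "systematic-2cM", "systematic-10cM"),
    n_individuals: int = 200,
    resamples_per_individual: int = 200,
    seed: int = 0,
    genome: Optional[GenomeModel] = None,
    include_unlinked: bool = True,
) -> ExperimentResult:
    """Bias and sampling variance of marker-subset estimates on a
    structured genome.

    For each simulated individual the truth is its tag-based (S, H_I) over
    all loci; for each marker count L and sampling regime,
    ``resamples_per_individual`` marker subsets are drawn and the
    diagnostic closed-form estimate computed on each.  Rows record the
    per-individual mean bias and sampling variance across resamples.  With
    ``include_unlinked`` the same crosses are also simulated with free
    recombination among as many unlinked markers (random sampling only),
    as the no-linkage reference.
    """
    genome = genome or GenomeModel()
    ss = np.random.SeedSequence([seed, 13])
    records = []

    def process(cross, label, individuals, genome_for_sampling, regs, sub_seed):
        het = np.stack([ind.tags[:, 0] != ind.tags[:, 1] for ind in individuals])
        anc = np.stack([(ind.tags == 2).mean(axis=1) for ind in individuals])
        true_s = anc.mean(axis=1)
        true_h = het.mean(axis=1)
        for L in L_values:
            for regime in regs:
                rng = np.random.default_rng(
                    np.random.SeedSequence([sub_seed, L, hash(regime) % 2**31])
                )
                subsets = np.stack(
                    [
                        sample_markers(genome_for_sampling, L, regime, rng)
                        for _ in range(resamples_per_individual)
                    ]
                )
                s_hat = anc[:, subsets].mean(axis=2)  # (n_ind, R)
                h_hat = het[:, subsets].mean(axis=2)
                for name, est, truth in (
                    ("S", s_hat, true_s),
                    ("H", h_hat, true_h),
                ):
                    bias = est.mean(axis=1) - truth
                    var = est.var(axis=1, ddof=1)
                    for i in range(len(individuals)):
                        records.append(
                            (cross, label, L, regime, i, f"bias_{name}", bias[i])
                        )
                        records.append(
                            (cross, label, L, regime, i, f"var_{name}", var[i])
                        )

    for c, cross in enumerate(cross_types):
        linked = simulate_cross(
            cross, genome=genome, n_individuals=n_individuals,
            seed=int(ss.spawn(1)[0].generate_state(1)[0] % 2**31),
        )
        process(cross, "linked", linked, genome, regimes, seed * 1000 + c)
        if include_unlinked:
            unlinked = simulate_cross(
                cross, n_loci=genome.n_loci, n_individuals=n_individuals,
                seed=int(ss.spawn(1)[0].generate_state(1)[0] % 2**31),
            )
            process(cross, "unlinked", unlinked, genome.n_loci, ["random"],
                    seed * 1000 + 500 + c)

    df = pd.DataFrame.from_records(
        records,
        columns=["cross", "genome", "L", "regime", "individual", "statistic", "value"],
    )
    df["replicate"] = 0
    return ExperimentResult(df)
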