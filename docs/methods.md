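# Methods

## Model

A diploid hybrid between two ancestral populations is described by the
genomic proportions `theta = (p11, p12, p22)` on the 2-simplex: the
fractions of its loci carrying two population-1 alleles, one allele from
each population, and two population-2 alleles.  The ancestry index
`S = p22 + p12/2` and interclass heterozygosity `H_I = p12` are linear
functions of `theta`, confined to the triangle `H_I <= 2*min(S, 1-S)`.

Conditional on `theta` and on known ancestral allele frequencies, each
locus's genotype is a three-component mixture (homozygote
`p11*f1^2 + p12*f1*f2 + p22*f2^2`, and the analogous heterozygote form),
so the per-locus probability is *linear in theta*.  The implementation
exploits this: a genotype is compiled once into an `(n_loci, 3)`
coefficient matrix, and any log-likelihood evaluation is a matrix-vector
product followed by a log-sum.  Dominant (band presence/absence) markers
compile the same way, band-absent rows being the recessive-homozygote
coefficients and band-present rows their complement.  The general-A
extension of the genotype probabilities (A >= 2 ancestral pools, pairwise
proportions `p_ab`) is provided as library functions; estimation itself
is two-population.

Model assumptions: ancestral allele frequencies are known constants;
founding alleles were drawn at random within each ancestral pool (no
Hardy–Weinberg assumption is made within the hybrid population); markers
are unlinked or sampled at random with respect to linkage.

### Orientation

`S` is everywhere the fraction of population-**2** ancestry (S=0 pure
population 1).  The closed-form estimator is accordingly
`S_hat = x22 + x12/2` where `x22` is the observed fraction of loci
homozygous for population-2 alleles.  All output columns are labelled
`S_pop2` to keep the orientation explicit.

## Numerical choices

* **Impossible states.**  A locus with probability 0 under `theta` makes
  the whole log-likelihood the finite sentinel `-1e308` rather than
  `-inf` or an exception.  Differences of sentinels are well defined, the
  sampler can move off impossible states, and an impossible class simply
  never wins a comparison.  `impossible_loci()` reports which loci are
  responsible.
* **Missing data** contribute nothing to the sum and reduce the
  effective locus count; a genotype must have at least one scored locus.
* **Validation, not clipping.**  Input frequencies must lie in [0, 1] and
  sum to 1 per (locus, population) within 1e-6; "diagnostic" means
  frequencies literally 1 and 0 at tolerance 1e-12.
* Natural logarithms throughout.  Multiallelic loci are supported;
  biallelic is the common case, not an assumption.

## Maximization

The likelihood is maximized by a deterministic triangular lattice
(default target 100 points, built from rows of constant `H_I` with
per-row counts proportional to row width; the three vertices are always
included) followed by a 1000-step Metropolis–Hastings chain started at
the best lattice point.  Proposals are `Dir(alpha * theta_cur)` with
concentration `alpha = 100`; because this kernel is asymmetric, the
acceptance ratio includes the proposal-density correction
`q(old|new)/q(new|old)`, making the trace a valid flat-prior posterior
sample as well as a maximizer.  Two boundary safeguards: per-component
proposal concentrations are floored at 1e-6 (a Dirichlet parameter of 0
is degenerate), and the chain itself starts a hair inside the simplex
because the proposal density diverges at exact-zero components; exact
boundary points still participate as arg-max candidates.

The reported MLE is the best state among closed-form candidate, lattice,
centroid and chain; ties keep the first visited and are counted.  When
every marker is diagnostic the closed form is the analytic arg-max, is
always evaluated first, and is restored if a chain state appears to beat
it within 1e-9 (floating-point rounding), so agreement with the closed
form is exact by construction.  Gradient-based optimizers are
deliberately absent: the surface is discontinuous at the simplex edge,
where much real data sits.

Batch estimation derives per-individual seeds from the root seed and the
row index via `SeedSequence`, and records per-individual failures in an
`error` column instead of aborting.

## Classification

The six early-generation classes are fixed points of `theta`:
P1=(1,0,0), P2=(0,0,1), F1=(0,1,0), F2=(1/4,1/2,1/4), B1=(1/2,1/2,0),
B2=(0,1/2,1/2).  Three criteria are offered:

* `classes-only`: accept the best class if it beats the runner-up by >2
  log-likelihood units (the a-priori six-category worldview);
* `AIC-only`: accept if the class AIC (k=1) is at most the continuous
  model's AIC (k=2), i.e. the class is within 1.0 log-likelihood unit of
  the MLE.  Exact equality is accepted — when the MLE coincides with a
  class point the class always wins on degrees of freedom.  The class AIC
  can never undercut the MLE AIC by more than 2;
* `strict-2LL-and-AIC` (default): both.  Failure of the first condition
  is reported as `ambiguous`, of the second as `rejected-by-MLE`.

When all markers are diagnostic, `classify` obtains the continuous
maximum from the closed form directly — provably identical to the
sampler's value and orders of magnitude faster; `estimator="mcmc"`
forces the sampler.  No multiple-testing correction is applied across a
sample; the planning rule `min_markers(n, alpha)` (smallest L with
`n * (1/2)^L <= alpha`) is surfaced as a design tool instead.

## Simulators

*Intermixture*: N founders, a fraction `mu` pure population 1, then
non-overlapping generations of random mating — parent pairs drawn with
replacement, so selfing is possible and no excess-homozygosity
correction is applied.  *Continent-island*: additionally, each offspring
is replaced by a pure parental immigrant (either population with
probability 1/2) with probability `m` per generation; replacement happens
after reproduction and before the next generation's mating, and reported
generations are the offspring *before* dispersal (the post-dispersal
populations are kept alongside).  One root seed spawns independent
streams for founding, mating, meiosis and immigration, so setting `m=0`
reproduces the closed swarm bit-for-bit.

Every allele copy carries its ancestral-population tag, so true S and
H_I are exact; at non-diagnostic loci founder (and immigrant) alleles
are drawn from the population's frequency distribution and inherited
thereafter.

The structured genome is 4 chromosomes x 2 arms x 50 loci at 2 cM
spacing, with exactly one crossover per arm per meiosis at a uniformly
chosen inter-locus interval (a deliberately minimal recombination model
for a highly structured genome).  The starting homolog is drawn
independently per arm, making arms exchangeable.  Controlled crosses
(F1, F2, B1, B2, Fk to k=10) start from fully diagnostic parental lines;
later generations breed within a pool whose size defaults to the
requested output size.

Marker sampling regimes: simple random without replacement, or
systematic walks at fixed cM intervals from a single random start,
wrapping across chromosomes in register order.

## Experiments and the packaged swarm

The default experiment input is a packaged synthetic swarm —
intermixture, N=100, mu=0.5, 20 generations, 65 diagnostic markers,
fixed seed — an old hybrid population in which any confident six-class
assignment is a false positive.  It emulates the dispersed joint
(S, H_I) distributions of long-admixed natural populations; it does not
emulate ongoing immigration, selection, genotyping error or uncertainty
in the parental frequencies, so passing tests speak to the estimator's
statistical behaviour under the stated model, not to robustness against
those processes.

*Subsampling*: for each marker count L and replicate, L markers are
drawn without replacement and every individual re-classified under each
criterion; raw per-individual 0/1 outcomes are stored and rates
recomputed on demand.  For diagnostic panels the per-subset decisions
are computed from locus-category counts in closed form (a vectorized
path shown by test to agree with `classify` case-by-case).

*Misspecification*: admixture is simulated in a small population (N=50,
10 generations) under one frequency scenario (diagnostic, 0.9/0.1,
0.8/0.2, 0.7/0.3, or the two mixed designs at L=50) and estimated under
another, with pure-parental controls drawn from the actual frequencies.
A single N=50 population drifts, so matched-scenario unbiasedness is a
statement about the average over replicate populations; near the
triangle's legs, estimates from weakly informative markers are pulled
inward (truncation at the boundary), which is a geometry effect, not an
estimator defect.

*Linkage bias/variance*: crosses on the structured genome (and unlinked
references), truth taken from all 400 loci, estimates from repeated
marker subsets under each regime; per-individual mean bias and sampling
variance across resamples are recorded.  Defaults (200 individuals, 200
resamples) are desk-scale; the counts are plain arguments for larger
runs.

## Problem sizes used in the shipped checks

The test suite and acceptance script use 1000 simulated F2s for the
false-F1 Monte Carlo, 500 pure-parental controls at 50 markers for the
misspecification benchmark, 255 swarm individuals at 65 markers for the
closed-form/sampler agreement check, N=1000 for first-generation class
frequencies, 200 individuals per cross for recovery checks, and 30
replicates over L in {3, 10, 60} for the false-classification-curve
shape.  These sizes give binomial/standard-error margins comfortably
inside the asserted tolerances.

## Known limitations

Parental allele frequencies are treated as known; jointly estimating
them with individual ancestries would require a hierarchical (Bayesian)
extension.  Support is summarized by 2-log-likelihood-unit regions, not
credible intervals.  Linked-marker *likelihoods* are not modelled (the
simulator has linkage; the estimator assumes markers exchangeable), and
dominant markers are markedly less informative about `H_I`, so more are
needed for comparable precision.
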