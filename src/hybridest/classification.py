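"""Likelihood-based tests of the six early-generation hybrid classes.

In the first two generations of admixture only six genotype-frequency
classes arise: the two parentals (P1, P2), the F1, the F2 and the two
first backcrosses (B1 towards P1, B2 towards P2).  Each class corresponds
to a fixed point in genomic-proportion space, so its likelihood is simply
the joint log-likelihood evaluated there.  A putative classification is
credible only if it both beats the other five classes decisively and is
not itself beaten by the unconstrained two-parameter MLE of (S, H_I); the
criteria below encode that comparison, together with a planning rule for
the number of diagnostic markers needed to keep spurious all-heterozygous
"F1" calls rare.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np

from .likelihood import (
    LOG_IMPOSSIBLE,
    AlleleFrequencyTable,
    CodominantGenotype,
    DominantPhenotype,
    GenomicProportions,
    closed_form_mle_diagnostic,
    codominant_coefficients,
    dominant_coefficients,
    indices_to_proportions,
    loglik_from_coefficients,
)
from .estimation import McmcConfig, mcmc_mle

__all__ = [
    "HYBRID_CLASSES",
    "CRITERIA",
    "ClassificationResult",
    "class_loglikelihoods",
    "classify",
    "min_markers",
    "expected_false_f1",
]

#: Expected genomic proportions (p11, p12, p22) of the six classes
#: produced in the first two generations of admixture.
HYBRID_CLASSES: dict[str, GenomicProportions] = {
    "P1": GenomicProportions(1.0, 0.0, 0.0),
    "P2": GenomicProportions(0.0, 0.0, 1.0),
    "F1": GenomicProportions(0.0, 1.0, 0.0),
    "F2": GenomicProportions(0.25, 0.5, 0.25),
    "B1": GenomicProportions(0.5, 0.5, 0.0),
    "B2": GenomicProportions(0.0, 0.5, 0.5),
}

CRITERIA = ("strict-2LL-and-AIC", "AIC-only", "classes-only")

_CLASS_THETAS = np.array([t.as_array() for t in HYBRID_CLASSES.values()])


@dataclasses.dataclass
class ClassificationResult:
    """Per-individual classification outcome.

    ``ll_gap`` is best-class minus second-best-class log-likelihood;
    ``delta_vs_mle`` is the (nonnegative) margin of the continuous MLE over
    the best class.  ``decision`` is ``classified-as-<class>``,
    ``ambiguous`` (best class not decisively better than the runner-up) or
    ``rejected-by-MLE`` (the continuous model wins on AIC).
    """

    class_loglik: dict[str, float]
    best_class: str
    second_class: str
    ll_gap: float
    mle_loglik: float
    delta_vs_mle: float
    decision: str
    criterion: str


def class_loglikelihoods(
    genotype: CodominantGenotype | DominantPhenotype,
    freqs: AlleleFrequencyTable,
    dominant: bool = False,
) -> dict[str, float]:
    """Joint log-likelihood of the genotype at each of the six class points.

    Classes under which the genotype is impossible evaluate to the
    ``LOG_IMPOSSIBLE`` sentinel and therefore never win a comparison.
    """
    if dominant:
        coef, _ = dominant_coefficients(genotype, freqs)
    else:
        coef, _ = codominant_coefficients(genotype, freqs)
    lls = loglik_from_coefficients(coef, _CLASS_THETAS)
    return {name: float(ll) for name, ll in zip(HYBRID_CLASSES, lls)}


def _decide(
    class_lls: dict[str, float], mle_loglik: float, criterion: str
) -> ClassificationResult:
    if criterion not in CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}; choose from {CRITERIA}")
    ranked = sorted(class_lls.items(), key=lambda kv: -kv[1])
    best, best_ll = ranked[0]
    second, second_ll = ranked[1]
    gap = best_ll - second_ll
    delta = max(0.0, mle_loglik - best_ll)

    # (i) best class beats the runner-up by more than 2 log-likelihood units
    distinct = gap > 2.0
    # (ii) AIC comparison, k=1 for a fixed class vs k=2 for the continuous
    # model: accept when AIC_class <= AIC_mle, i.e. best_ll >= mle_ll - 1.
    # Exact equality (class point = MLE) is accepted: the class then always
    # wins on degrees of freedom.
    aic_ok = best_ll >= mle_loglik - 1.0 - 1e-9

    if criterion == "classes-only":
        decision = f"classified-as-{best}" if distinct else "ambiguous"
    elif criterion == "AIC-only":
        decision = f"classified-as-{best}" if aic_ok else "rejected-by-MLE"
    else:  # strict: both conditions
        if not distinct:
            decision = "ambiguous"
        elif not aic_ok:
            decision = "rejected-by-MLE"
        else:
            decision = f"classified-as-{best}"
    return ClassificationResult(
        class_loglik=dict(class_lls),
        best_class=best,
        second_class=second,
        ll_gap=gap,
        mle_loglik=mle_loglik,
        delta_vs_mle=delta,
        decision=decision,
        criterion=criterion,
    )


def _diagnostic_mle_loglik(
    genotype: CodominantGenotype, freqs: AlleleFrequencyTable
) -> float:
    """Continuous-model maximum log-likelihood for all-diagnostic markers.

    Equals the sampler's result exactly: the closed form is the analytic
    arg-max of the likelihood and the sampler always evaluates it as a
    candidate, so the maximum it reports can be neither above nor below
    this value.
    """
    cf = closed_form_mle_diagnostic(genotype, freqs)
    coef, _ = codominant_coefficients(genotype, freqs)
    return float(
        loglik_from_coefficients(coef, indices_to_proportions(cf).as_array())
    )


def classify(
    genotype: CodominantGenotype | DominantPhenotype,
    freqs: AlleleFrequencyTable,
    config: Optional[McmcConfig] = None,
    criterion: str = "strict-2LL-and-AIC",
    dominant: bool = False,
    estimator: str = "auto",
) -> ClassificationResult:
    """Test whether one of the six early-generation classes fits as well as
    the continuous (S, H_I) MLE.

    ``estimator='auto'`` uses the exact closed-form maximum when every
    marker is diagnostic (provably identical to the sampler's result) and
    the grid + MCMC maximizer otherwise; ``estimator='mcmc'`` forces the
    sampler.
    """
    if estimator not in ("auto", "mcmc"):
        raise ValueError("estimator must be 'auto' or 'mcmc'")
    lls = class_loglikelihoods(genotype, freqs, dominant=dominant)
    use_closed_form = (
        estimator == "auto"
        and not dominant
        and isinstance(genotype, CodominantGenotype)
        and freqs.all_diagnostic([l for l, _ in genotype.non_missing()])
    )
    if use_closed_form:
        mle_ll = _diagnostic_mle_loglik(genotype, freqs)
    else:
        mle_ll = mcmc_mle(genotype, freqs, config, dominant=dominant).max_loglik
    return _decide(lls, mle_ll, criterion)


def min_markers(n: int, alpha_err: float) -> int:
    """Smallest number of diagnostic markers L with n * (1/2)**L <= alpha_err.

    This keeps the expected number of individuals, among ``n`` screened
    later-generation hybrids, that are all-heterozygous by chance (and so
    would be called F1) at or below the experiment-wise error ``alpha_err``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 < alpha_err < 1.0):
        raise ValueError("alpha_err must be in (0, 1)")
    L = max(0, math.ceil((math.log(n) - math.log(alpha_err)) / math.log(2.0)))
    while L > 0 and n * 0.5 ** (L - 1) <= alpha_err:
        L -= 1
    while n * 0.5**L > alpha_err:
        L += 1
    return L


def expected_false_f1(n: int, L: int) -> float:
    """Expected count of all-heterozygous genotypes (spurious F1 calls)
    among ``n`` true F2s scored at ``L`` diagnostic markers: n * (1/2)**L."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if L < 0:
        raise ValueError("L must be >= 0")
    return n * 0.5**L
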