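"""Maximum-likelihood estimation of (S, H_I) over the triangular sample space.

The joint log-likelihood is maximized with a two-stage strategy: a coarse
deterministic lattice over the triangle locates a starting point, and a
Metropolis-Hastings random walk with Dirichlet proposals centred on the
current genomic proportions refines it.  The best-likelihood state visited
anywhere (lattice, closed-form candidate, or chain) is reported as the MLE.
A quasi-Newton optimizer is deliberately not offered: the likelihood
surface is discontinuous at the simplex boundary, where gradient-based
steps are unreliable, while the sampler handles edges without trouble.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Mapping, Sequence
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .likelihood import (
    LOG_IMPOSSIBLE,
    AlleleFrequencyTable,
    CodominantGenotype,
    DominantPhenotype,
    GenomicProportions,
    HybridIndices,
    closed_form_mle_diagnostic,
    codominant_coefficients,
    dominant_coefficients,
    indices_to_proportions,
    loglik_from_coefficients,
    proportions_to_indices,
)

__all__ = [
    "McmcConfig",
    "LikelihoodSurface",
    "EstimationResult",
    "EstimationError",
    "triangle_lattice",
    "likelihood_surface",
    "mcmc_mle",
    "estimate_sample",
]


class EstimationError(RuntimeError):
    """Raised when no feasible starting point exists for a genotype."""

    def __init__(self, message: str, loci: Sequence[str] = ()):
        super().__init__(message)
        self.loci = list(loci)


@dataclasses.dataclass(frozen=True)
class McmcConfig:
    """Configuration of the grid + Metropolis-Hastings maximizer.

    ``alpha_prop`` is the Dirichlet proposal concentration (larger values
    concentrate proposals near the current state); it is unrelated to any
    error rate.  ``concentration_floor`` keeps the per-component proposal
    concentration away from zero so that chains at the simplex boundary
    still propose valid moves.
    """

    steps: int = 1000
    alpha_prop: float = 100.0
    grid_points: int = 100
    seed: int = 0
    concentration_floor: float = 1e-6

    def __post_init__(self):
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.alpha_prop <= 0:
            raise ValueError("alpha_prop must be > 0")
        if self.grid_points < 3:
            raise ValueError("grid_points must be >= 3")
        if self.concentration_floor <= 0:
            raise ValueError("concentration_floor must be > 0")


def triangle_lattice(grid_points: int) -> list[HybridIndices]:
    """Deterministic lattice of (S, H_I) points covering the triangle.

    The lattice is built from ``r`` rows of constant H_I (H_I = i/(r-1)),
    with per-row point counts proportional to the row's width so that the
    total is close to ``grid_points``.  The three vertices (0,0), (1,0) and
    (0.5,1) are always included; ``grid_points=3`` yields exactly them.
    """
    if grid_points < 3:
        raise ValueError("grid_points must be >= 3")
    r = max(2, round((math.sqrt(8 * grid_points + 1) - 1) / 2))
    widths = np.arange(r, 0, -1, dtype=float)  # row i has weight r - i
    scale = grid_points / widths.sum()
    points: list[HybridIndices] = []
    for i in range(r):
        h = i / (r - 1)
        k = max(1, round(widths[i] * scale))
        if i == 0:
            k = max(2, k)  # bottom row must reach both (0,0) and (1,0)
        if i == r - 1:
            k = 1  # apex row collapses to (0.5, 1)
        if k == 1:
            points.append(HybridIndices(0.5, h))
            continue
        lo, hi = h / 2.0, 1.0 - h / 2.0
        for j in range(k):
            s = lo + (hi - lo) * j / (k - 1)
            points.append(HybridIndices(s, h))
    return points


def _lattice_thetas(points: Sequence[HybridIndices]) -> np.ndarray:
    return np.array([indices_to_proportions(p).as_array() for p in points])


@dataclasses.dataclass
class LikelihoodSurface:
    """Log-likelihood evaluated on a regular (S, H_I) lattice."""

    points: pd.DataFrame  # columns: S, H_I, loglik
    resolution: float

    @property
    def max_loglik(self) -> float:
        return float(self.points["loglik"].max())

    @property
    def argmax(self) -> HybridIndices:
        row = self.points.loc[self.points["loglik"].idxmax()]
        return HybridIndices(float(row["S"]), float(row["H_I"]))

    def support_region(self, delta: float = 2.0) -> pd.DataFrame:
        """Lattice points within ``delta`` log-likelihood units of the
        maximum (the 'black' region of a shaded surface plot)."""
        return self.points[self.points["loglik"] >= self.max_loglik - delta]


def _coefficients(genotype, freqs, dominant: bool):
    if dominant:
        if not isinstance(genotype, DominantPhenotype):
            raise TypeError("dominant=True requires a DominantPhenotype")
        return dominant_coefficients(genotype, freqs)
    if not isinstance(genotype, CodominantGenotype):
        raise TypeError("expected a CodominantGenotype (or pass dominant=True)")
    return codominant_coefficients(genotype, freqs)


def likelihood_surface(
    genotype: CodominantGenotype | DominantPhenotype,
    freqs: AlleleFrequencyTable,
    resolution: float = 0.02,
    dominant: bool = False,
) -> LikelihoodSurface:
    """Evaluate the joint log-likelihood on a regular triangular lattice."""
    if not (0 < resolution <= 0.5):
        raise ValueError("resolution must be in (0, 0.5]")
    coef, _ = _coefficients(genotype, freqs, dominant)
    grid = np.arange(0.0, 1.0 + resolution / 2, resolution)
    ss, hh = np.meshgrid(grid, grid)
    mask = hh <= 2.0 * np.minimum(ss, 1.0 - ss) + 1e-9
    s, h = ss[mask], hh[mask]
    thetas = np.column_stack([1.0 - s - h / 2, h, s - h / 2])
    thetas = np.clip(thetas, 0.0, None)
    lls = loglik_from_coefficients(coef, thetas)
    df = pd.DataFrame({"S": s, "H_I": h, "loglik": lls})
    return LikelihoodSurface(points=df, resolution=resolution)


@dataclasses.dataclass
class EstimationResult:
    """Outcome of a single-genotype maximization."""

    mle: GenomicProportions
    indices: HybridIndices
    max_loglik: float
    start_point: HybridIndices
    n_ties: int = 1
    accept_rate: float = float("nan")
    trace: Optional[list[tuple[tuple[float, float, float], float, bool]]] = None


def _dirichlet_logpdf(x: np.ndarray, alpha: np.ndarray) -> float:
    xs = np.clip(x, 1e-300, None)
    return float(
        gammaln(alpha.sum()) - gammaln(alpha).sum() + ((alpha - 1.0) * np.log(xs)).sum()
    )


def mcmc_mle(
    genotype: CodominantGenotype | DominantPhenotype,
    freqs: AlleleFrequencyTable,
    config: Optional[McmcConfig] = None,
    dominant: bool = False,
    store_trace: bool = False,
) -> EstimationResult:
    """Joint MLE of (p11, p12, p22) by lattice start + Metropolis-Hastings.

    The chain starts at the best lattice point, proposes from a Dirichlet
    distribution Dir(alpha_prop * theta) centred on the current state
    (component concentrations floored at ``concentration_floor``), and
    accepts with the Metropolis-Hastings ratio including the proposal
    density correction for the asymmetric Dirichlet kernel.  The reported
    MLE is the highest-likelihood state among every candidate evaluated:
    the closed-form estimate when all loci are diagnostic (making agreement
    with the closed form exact by construction), the lattice, the simplex
    centroid, and all chain states.  Ties keep the first state visited.
    """
    config = config or McmcConfig()
    coef, loci = _coefficients(genotype, freqs, dominant)
    dead = (coef <= 0.0).all(axis=1)
    if dead.any():
        bad = [l for l, d in zip(loci, dead) if d]
        raise EstimationError(
            f"genotype impossible at every point of the sample space; "
            f"offending loci: {bad}",
            loci=bad,
        )

    lattice = triangle_lattice(config.grid_points)
    thetas = _lattice_thetas(lattice)
    lls = loglik_from_coefficients(coef, thetas)

    best_theta: Optional[np.ndarray] = None
    best_indices: Optional[HybridIndices] = None
    best_ll = -np.inf
    n_ties = 1

    # Closed-form candidate first: for all-diagnostic marker sets it is the
    # analytic arg-max, so evaluating it first guarantees exact agreement.
    if not dominant and freqs.all_diagnostic([l for l, _ in genotype.non_missing()]):
        cf = closed_form_mle_diagnostic(genotype, freqs)
        cf_theta = indices_to_proportions(cf).as_array()
        cf_ll = float(loglik_from_coefficients(coef, cf_theta))
        best_theta = cf_theta
        best_indices = cf
        best_ll = cf_ll
    else:
        cf = None

    centroid = np.full(3, 1.0 / 3.0)
    cand_thetas = np.vstack([thetas, centroid[None, :]])
    cand_lls = np.append(lls, loglik_from_coefficients(coef, centroid))
    for th, ll in zip(cand_thetas, cand_lls):
        if ll > best_ll:
            best_theta, best_ll, n_ties = th, float(ll), 1
            best_indices = None
        elif ll == best_ll and best_theta is not None:
            n_ties += 1

    if best_ll <= LOG_IMPOSSIBLE:
        raise EstimationError(
            "genotype impossible at every evaluated starting point", loci=loci
        )

    # chain starts at the best *lattice* point (fall back to centroid)
    start_i = int(np.argmax(cand_lls))
    start_theta = cand_thetas[start_i].copy()
    start_ll = float(cand_lls[start_i])
    start_point = proportions_to_indices(GenomicProportions.from_array(start_theta))

    rng = np.random.default_rng(config.seed)
    # the chain itself starts a hair inside the simplex: the Dirichlet
    # proposal density diverges at exact-zero components, so boundary
    # lattice points are kept as candidates but not as chain states
    cur = np.clip(start_theta, 1e-9, None)
    cur /= cur.sum()
    cur_ll = float(loglik_from_coefficients(coef, cur))
    trace = [] if store_trace else None
    n_accept = 0
    for _ in range(config.steps):
        alpha_fwd = np.maximum(config.alpha_prop * cur, config.concentration_floor)
        prop = rng.dirichlet(alpha_fwd)
        prop = np.clip(prop, 1e-12, None)
        prop /= prop.sum()
        prop_ll = float(loglik_from_coefficients(coef, prop))
        alpha_rev = np.maximum(config.alpha_prop * prop, config.concentration_floor)
        log_ratio = (
            prop_ll
            - cur_ll
            + _dirichlet_logpdf(cur, alpha_rev)
            - _dirichlet_logpdf(prop, alpha_fwd)
        )
        accepted = math.log(rng.random()) < log_ratio
        if accepted:
            cur, cur_ll = prop, prop_ll
            n_accept += 1
        if cur_ll > best_ll:
            best_theta, best_ll, n_ties = cur, cur_ll, 1
            best_indices = None
        elif cur_ll == best_ll and not np.array_equal(cur, best_theta):
            n_ties += 1
        if trace is not None:
            trace.append((tuple(cur), cur_ll, accepted))

    # A chain state can edge past the analytic arg-max by a few ulp of
    # floating-point rounding; within tolerance the closed form stands.
    if cf is not None and best_indices is None and best_ll - cf_ll <= 1e-9:
        best_theta, best_indices = cf_theta, cf
    mle = GenomicProportions.from_array(best_theta)
    return EstimationResult(
        mle=mle,
        indices=best_indices if best_indices is not None else proportions_to_indices(mle),
        max_loglik=best_ll,
        start_point=start_point,
        n_ties=n_ties,
        accept_rate=n_accept / config.steps,
        trace=trace,
    )


def _derived_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([int(seed), int(index)]).generate_state(1)[0] % (2**31))


def estimate_sample(
    genotypes: Mapping[str, CodominantGenotype | DominantPhenotype]
    | Sequence[CodominantGenotype | DominantPhenotype],
    freqs: AlleleFrequencyTable,
    config: Optional[McmcConfig] = None,
    dominant: bool = False,
) -> pd.DataFrame:
    """Independent per-individual estimation over a sample.

    Per-individual seeds derive deterministically from ``config.seed`` and
    the row index.  Failures are recorded in the ``error`` column rather
    than aborting the batch.  The ``S_pop2`` column is the fraction of
    population-2 ancestry (S = 0 means pure population 1).
    """
    config = config or McmcConfig()
    if isinstance(genotypes, Mapping):
        items = list(genotypes.items())
    else:
        items = [(str(i), g) for i, g in enumerate(genotypes)]
    if not items:
        raise ValueError("estimate_sample requires at least one individual")
    rows = []
    for i, (ident, g) in enumerate(items):
        cfg = dataclasses.replace(config, seed=_derived_seed(config.seed, i))
        try:
            res = mcmc_mle(g, freqs, cfg, dominant=dominant)
            rows.append(
                {
                    "id": ident,
                    "S_pop2": res.indices.S,
                    "H_I": res.indices.H_I,
                    "p11": res.mle.p11,
                    "p12": res.mle.p12,
                    "p22": res.mle.p22,
                    "max_loglik": res.max_loglik,
                    "error": None,
                }
            )
        except (EstimationError, ValueError, KeyError) as exc:
            rows.append(
                {
                    "id": ident,
                    "S_pop2": np.nan,
                    "H_I": np.nan,
                    "p11": np.nan,
                    "p12": np.nan,
                    "p22": np.nan,
                    "max_loglik": np.nan,
                    "error": str(exc),
                }
            )
    return pd.DataFrame(rows)
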