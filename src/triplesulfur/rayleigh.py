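"""Closed-system Rayleigh distillation and fractionation-factor estimation.

The reactant in a closed system with a single loss pathway of fractionation
factor α evolves as

    δ_R(f) = (δ_R,0 + 1000) · f^(α−1) − 1000,

where f is the mole fraction of reactant remaining.  The accumulated product
follows from isotope mass balance between the initial inventory and the
residual reactant.  Three per-time-point estimators invert these relations:

``reactant``
    uses the measured residual-reactant composition and f;
``product``
    uses the measured accumulated-product composition and f (reactant
    composition at t = 0 only);
``paired``
    solves α from the joint relation between the measured residual reactant
    and the measured accumulated product at known f,

        (δ_P + 1000)/(δ_R + 1000) = (1 − f^α) / ((1 − f) · f^(α−1)),

    using both compositions and therefore insensitive to a common offset.

Per-point estimates are averaged with equal weights; the spread across time
points is reported as the 1σ uncertainty.  λ uncertainties are propagated by
seeded Monte Carlo over Gaussian perturbations of the input compositions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .core import (
    FractionationFactor,
    IsotopeComposition,
    SulfurPool,
    UndefinedLambdaError,
    lambda_between,
    mix,
)

__all__ = [
    "DistillationState",
    "reactant_delta",
    "product_delta",
    "distill_pools",
    "fit_epsilon34",
    "fit_lambda33",
    "propagate_lambda_error",
]


@dataclass(frozen=True)
class DistillationState:
    """Snapshot of a closed-system distillation at reactant fraction ``f``."""

    f: float
    reactant: SulfurPool
    product: SulfurPool
    initial_reactant: SulfurPool
    initial_product: SulfurPool | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.f <= 1.0:
            raise ValueError(f"f must lie in (0, 1] (got {self.f})")


def _alpha_scalar(alpha, isotope: int) -> float:
    if isinstance(alpha, FractionationFactor):
        return alpha.alpha(isotope)
    return float(alpha)


def reactant_delta(delta0: float, f: float, alpha, isotope: int = 34) -> float:
    """Residual-reactant δ (‰) at fraction remaining ``f``.

    ``alpha`` may be a :class:`FractionationFactor` (³⁴α applied for
    ``isotope=34``, ³⁴α^³³λ for ``isotope=33``) or a bare scalar α.
    """
    if not 0.0 < f <= 1.0:
        raise ValueError(f"f must lie in (0, 1] (got {f})")
    a = _alpha_scalar(alpha, isotope)
    return (delta0 + 1000.0) * f ** (a - 1.0) - 1000.0


def product_delta(
    delta_r0: float,
    f: float,
    alpha,
    isotope: int = 34,
    r0: float = 1.0,
    p0: float = 0.0,
    delta_p0: float = 0.0,
) -> float:
    """Accumulated-product δ (‰) at fraction remaining ``f``.

    Mass balance between the initial inventory (reactant ``r0`` at
    ``delta_r0`` plus any pre-existing product ``p0`` at ``delta_p0``) and
    the residual reactant from the Rayleigh relation:

        δ_P + 1000 = [r0·(δ_R0+1000)·(1 − f^α) + p0·(δ_P0+1000)]
                     / (r0·(1 − f) + p0).
    """
    if not 0.0 < f <= 1.0:
        raise ValueError(f"f must lie in (0, 1] (got {f})")
    a = _alpha_scalar(alpha, isotope)
    produced = r0 * (1.0 - f) + p0
    if produced <= 0.0:
        raise ValueError("no product exists: r0*(1-f) + p0 must be positive")
    one_minus_fa = -math.expm1(a * math.log(f))  # precise for f near 1
    x = (
        r0 * (delta_r0 + 1000.0) * one_minus_fa
        + p0 * (delta_p0 + 1000.0)
    ) / produced
    return x - 1000.0


def distill_pools(
    reactant0: SulfurPool,
    f: float,
    ff: FractionationFactor,
    product_species: str = "sulfide",
    product0: SulfurPool | None = None,
) -> DistillationState:
    """Distill a pool to fraction ``f``, with exact isotope-mole bookkeeping.

    The residual reactant follows the Rayleigh relation for both isotopes;
    the accumulated product carries exactly the isotopologue moles removed,
    so ``mix([residual, product])`` returns the initial inventory to machine
    precision.
    """
    if reactant0.comp is None:
        raise ValueError("initial reactant needs an isotope composition")
    d34 = reactant_delta(reactant0.comp.delta34, f, ff, 34)
    d33 = reactant_delta(reactant0.comp.delta33, f, ff, 33)
    residual = SulfurPool(
        reactant0.species,
        reactant0.conc * f,
        None,
        IsotopeComposition(d34, d33, reactant0.comp.frame),
    )
    # product = (initial inventory) - (residual), isotopologue by isotopologue
    initial_pools = [reactant0] + ([product0] if product0 is not None else [])
    n32 = n33 = n34 = 0.0
    for pool, sign in [(p, 1.0) for p in initial_pools] + [(residual, -1.0)]:
        r33, r34 = pool.comp.ratios()
        p32 = pool.conc / (1.0 + r33 + r34)
        n32 += sign * p32
        n33 += sign * p32 * r33
        n34 += sign * p32 * r34
    if n32 <= 0.0:
        raise ValueError("no product exists at f = 1 with no initial product")
    comp = IsotopeComposition.from_ratios(
        n33 / n32, n34 / n32, reactant0.comp.frame
    )
    product = SulfurPool(
        product_species, reactant0.conc * (1.0 - f) + (product0.conc if product0 else 0.0),
        None, comp,
    )
    return DistillationState(f, residual, product, reactant0, product0)


def _eps_reactant(f: float, delta: float, delta0: float) -> float:
    return 1000.0 * math.log((delta + 1000.0) / (delta0 + 1000.0)) / math.log(f)


def _eps_product(
    f: float, delta: float, delta0: float, r0: float, p0: float, delta_p0: float
) -> float:
    produced = r0 * (1.0 - f) + p0
    fa = (
        r0 * (delta0 + 1000.0)
        - (delta + 1000.0) * produced
        + p0 * (delta_p0 + 1000.0)
    ) / (r0 * (delta0 + 1000.0))
    if fa <= 0.0:
        raise ValueError(
            "product composition inconsistent with any closed-system alpha"
        )
    return 1000.0 * (math.log(fa) / math.log(f) - 1.0)


def _eps_paired(f: float, delta_r: float, delta_p: float) -> float:
    target = (delta_p + 1000.0) / (delta_r + 1000.0)

    def g(a: float) -> float:
        return (1.0 - f ** a) / ((1.0 - f) * f ** (a - 1.0)) - target

    return (brentq(g, 0.5, 1.5, xtol=1e-12) - 1.0) * 1000.0


def fit_epsilon34(
    f,
    delta,
    role: str = "reactant",
    delta0: float = 0.0,
    r0: float = 1.0,
    p0: float = 0.0,
    delta_p0: float = 0.0,
    delta_reactant=None,
    min_consumed: float = 0.01,
    weights: str = "equal",
) -> FractionationFactor:
    """Estimate ³⁴ε from a time series of (f, δ³⁴S) observations.

    Parameters
    ----------
    f, delta
        Arrays of fraction-remaining and the observed δ³⁴S of the pool named
        by ``role``.  For ``role="paired"`` pass the product series in
        ``delta`` and the residual-reactant series in ``delta_reactant``.
    role
        ``"reactant"``, ``"product"`` or ``"paired"`` (see module docstring).
    delta0, r0, p0, delta_p0
        Initial reactant composition and inventory sizes (product roles).
    min_consumed
        Points with 1 − f below this threshold are excluded: ε is
        ill-conditioned when almost nothing has reacted.
    weights
        ``"equal"`` (default, the published convention) or
        ``"inverse_variance"``: for the reactant role a fixed δ-noise maps
        onto ε with variance ∝ 1/ln²f, so weighting by ln²f down-weights
        barely-consumed points.

    Returns
    -------
    FractionationFactor
        Equal-weight mean of the per-point estimates; the standard deviation
        across time points is attached as the 1σ uncertainty (``None`` for a
        single usable point).
    """
    f = np.atleast_1d(np.asarray(f, dtype=float))
    delta = np.atleast_1d(np.asarray(delta, dtype=float))
    if role == "paired":
        if delta_reactant is None:
            raise ValueError("role='paired' requires delta_reactant")
        delta_reactant = np.atleast_1d(np.asarray(delta_reactant, dtype=float))

    eps, w = [], []
    for i in range(len(f)):
        if 1.0 - f[i] < min_consumed:
            continue
        if role == "reactant":
            eps.append(_eps_reactant(f[i], delta[i], delta0))
        elif role == "product":
            eps.append(_eps_product(f[i], delta[i], delta0, r0, p0, delta_p0))
        elif role == "paired":
            eps.append(_eps_paired(f[i], delta_reactant[i], delta[i]))
        else:
            raise ValueError(f"unknown role {role!r}")
        if weights == "equal":
            w.append(1.0)
        elif weights == "inverse_variance":
            w.append(math.log(f[i]) ** 2 if role == "reactant" else 1.0)
        else:
            raise ValueError(f"unknown weights {weights!r}")
    if not eps:
        raise ValueError(
            "no usable time points: all f exceed 1 - min_consumed"
        )
    eps = np.asarray(eps)
    w = np.asarray(w)
    mean = float(np.average(eps, weights=w))
    sd = (
        float(np.sqrt(np.average((eps - mean) ** 2, weights=w) * len(eps) / (len(eps) - 1)))
        if len(eps) > 1
        else None
    )
    return FractionationFactor.from_epsilon(mean, sd_epsilon34=sd)


def fit_lambda33(
    reactant,
    product,
    sd_delta34: float = 0.0,
    sd_capdelta33: float = 0.0,
    n_draws: int = 10_000,
    seed: int = 0,
    min_separation: float = 0.05,
) -> FractionationFactor:
    """³³λ (with Monte-Carlo 1σ) between reactant and product compositions.

    ``reactant`` and ``product`` may be single :class:`IsotopeComposition`
    objects or equal-length sequences (per-time-point pairs, averaged with
    equal weights).  λ is computed pairwise with :func:`lambda_between`.
    """
    r_list = [reactant] if isinstance(reactant, IsotopeComposition) else list(reactant)
    p_list = [product] if isinstance(product, IsotopeComposition) else list(product)
    if len(r_list) != len(p_list):
        raise ValueError("reactant and product series must have equal length")

    lams, alphas = [], []
    for a, b in zip(r_list, p_list):
        if abs(a.delta34 - b.delta34) < min_separation:
            raise UndefinedLambdaError(
                f"delta34 separation {abs(a.delta34 - b.delta34):.3g} below "
                f"tolerance {min_separation}"
            )
        lams.append(lambda_between(a, b))
        alphas.append((a.delta34 + 1000.0) / (b.delta34 + 1000.0))

    sd_lam = None
    if sd_delta34 > 0.0 or sd_capdelta33 > 0.0:
        draws = [
            propagate_lambda_error(
                a, b, sd_delta34, sd_capdelta33, n_draws=n_draws, seed=seed + k
            )
            for k, (a, b) in enumerate(zip(r_list, p_list))
        ]
        # average the per-pair MC variances, then fold in between-pair spread
        within = float(np.mean(np.square(draws))) / len(draws)
        between = float(np.var(lams, ddof=1)) / len(lams) if len(lams) > 1 else 0.0
        sd_lam = math.sqrt(within + between)
    elif len(lams) > 1:
        sd_lam = float(np.std(lams, ddof=1))

    return FractionationFactor(
        alpha34=float(np.mean(alphas)),
        lambda33=float(np.mean(lams)),
        sd_lambda33=sd_lam,
    )


def propagate_lambda_error(
    a: IsotopeComposition,
    b: IsotopeComposition,
    sd_delta34: float = 0.2,
    sd_capdelta33: float = 0.01,
    n_draws: int = 10_000,
    seed: int = 0,
) -> float:
    """1σ of λ under Gaussian perturbation of both (δ³⁴S, Δ³³S) pairs.

    Deterministic for a given ``seed``.  The uncertainty on λ grows steeply
    as the δ³⁴S separation between the pools shrinks.
    """
    if sd_delta34 < 0.0 or sd_capdelta33 < 0.0:
        raise ValueError("sigmas must be non-negative")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if sd_delta34 == 0.0 and sd_capdelta33 == 0.0:
        return 0.0
    rng = np.random.default_rng(seed)
    lams = np.empty(n_draws)
    for k in range(n_draws):
        pa = IsotopeComposition.from_capdelta(
            a.delta34 + rng.normal(0.0, sd_delta34),
            a.capdelta33 + rng.normal(0.0, sd_capdelta33),
            a.frame,
        )
        pb = IsotopeComposition.from_capdelta(
            b.delta34 + rng.normal(0.0, sd_delta34),
            b.capdelta33 + rng.normal(0.0, sd_capdelta33),
            b.frame,
        )
        lams[k] = lambda_between(pa, pb)
    return float(np.std(lams, ddof=1))
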