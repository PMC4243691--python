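"""Dataset-level analysis recipes tying the estimation modules together.

These are the standard ways the batch-experiment tables are reduced to
fractionation factors:

* sulfate experiments print per-time-point ³⁴ε directly (no per-point δ
  columns); the recipe reconstructs the implied accumulated-product
  composition from each printed (ε, f) pair with the product relation and
  re-fits, which averages the printed values with equal weights;
* the thiosulfate experiment prints residual-reactant (both thiosulfate
  sites) and product-sulfide compositions: the wholesale-reduction ³⁴ε uses
  the paired estimator on bulk thiosulfate vs sulfide with the
  product-based consumed fraction — the same construction applied to a
  single site gives the site-specific pathway estimates;
* triple-isotope λ comes from pairwise reactant/product compositions, with
  bulk thiosulfate formed by equal-mole ratio-space mixing of its sites.
"""

from __future__ import annotations

from .core import (
    FractionationFactor,
    IsotopeComposition,
    SulfurPool,
    lambda_between,
    mix,
)
from .mass_balance import ExperimentDataset
from .rayleigh import fit_epsilon34, product_delta

__all__ = [
    "epsilon_from_printed",
    "epsilon_thiosulfate",
    "bulk_thiosulfate",
    "lambda_thiosulfate_bulk",
]


def epsilon_from_printed(ds: ExperimentDataset) -> FractionationFactor:
    """Mean ³⁴ε of a dataset carrying printed per-point ε annotations.

    Each printed (ε, f) pair implies an accumulated-product δ³⁴S through
    the closed-system product relation; re-fitting those compositions in
    the product role recovers each per-point ε exactly, so the result is
    the equal-weight mean and spread of the printed values.
    """
    fs, deltas = [], []
    for tp in ds.points:
        eps = tp.extras.get("eps34")
        f_pct = tp.extras.get("f_pct")
        if eps is None or f_pct is None:
            continue
        f = 1.0 - f_pct / 100.0
        fs.append(f)
        deltas.append(
            product_delta(0.0, f, FractionationFactor.from_epsilon(eps))
        )
    if not fs:
        raise ValueError("dataset carries no printed per-point epsilon values")
    return fit_epsilon34(fs, deltas, role="product")


def bulk_thiosulfate(tp) -> SulfurPool | None:
    """Equal-mole ratio-space mixture of the thiosulfate sites, if measured."""
    son = tp.pool("thiosulfate_sulfonate")
    sane = tp.pool("thiosulfate_sulfane")
    if son is None or sane is None or son.comp is None or sane.comp is None:
        return None
    return mix(
        [
            SulfurPool(son.species, 1.0, None, son.comp),
            SulfurPool(sane.species, 1.0, None, sane.comp),
        ]
    )


def epsilon_thiosulfate(
    ds: ExperimentDataset, reactant: str = "bulk"
) -> FractionationFactor:
    """³⁴ε of thiosulfate reduction to sulfide by the paired estimator.

    ``reactant`` selects the assumed precursor pool: ``"bulk"`` (wholesale,
    non-site-specific reduction), ``"sulfonate"`` or ``"sulfane"``
    (site-specific pathways).  Each time point with both compositions
    yields one estimate from the joint residual-reactant/accumulated-
    product relation at f = 1 − [sulfide S]/[acceptor S]₀; estimates are
    averaged with equal weights.
    """
    f, d_r, d_p = [], [], []
    for tp in ds.points:
        hs = tp.pool("sulfide")
        if hs is None or hs.comp is None:
            continue
        if reactant == "bulk":
            pool = bulk_thiosulfate(tp)
        elif reactant == "sulfonate":
            pool = tp.pool("thiosulfate_sulfonate")
        elif reactant == "sulfane":
            pool = tp.pool("thiosulfate_sulfane")
        else:
            raise ValueError(
                "reactant must be 'bulk', 'sulfonate' or 'sulfane'"
            )
        if pool is None or pool.comp is None:
            continue
        f.append(1.0 - hs.conc / ds.initial_acceptor_S)
        d_r.append(pool.comp.delta34)
        d_p.append(hs.comp.delta34)
    if not f:
        raise ValueError("no time points with both reactant and product isotopes")
    return fit_epsilon34(f, d_p, role="paired", delta_reactant=d_r)


def lambda_thiosulfate_bulk(
    table4: dict, experiment: str, t: float
) -> float:
    """Pairwise ³³λ between bulk thiosulfate and sulfide at one time point.

    ``table4`` is the composition dictionary keyed (experiment, t, species)
    as returned by :func:`triplesulfur.synthetic.load_table4`.
    """
    son = table4[(experiment, t, "thiosulfate_sulfonate")]
    sane = table4[(experiment, t, "thiosulfate_sulfane")]
    sulfide = table4[(experiment, t, "sulfide")]
    bulk = mix(
        [
            SulfurPool("thiosulfate_sulfonate", 1.0, None, son),
            SulfurPool("thiosulfate_sulfane", 1.0, None, sane),
        ]
    )
    return lambda_between(bulk.comp, sulfide)
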