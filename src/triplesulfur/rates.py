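"""Cell-specific reduction rates and consumption fractions.

Rates are reported in fmol of sulfur reduced per cell per day, computed
between adjacent sampling times from the change in concentration divided by
elapsed time and a cell-density statistic for the interval.  The default
statistic, ``half_delta`` (half the change in cell count over the interval),
is the convention that reproduces the published per-interval rate columns
of the packaged batch-experiment tables to within rounding of the printed
concentrations; arithmetic-mean, start-of-interval and logarithmic-mean
statistics are available as alternatives.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .mass_balance import ExperimentDataset, TimePoint

__all__ = ["cs_rate", "fraction_consumed", "CELL_STATISTICS"]

#: mM per day per (cells/mL)  ->  fmol per cell per day:
#: 1 mM = 1e12 fmol/L and cells/mL = 1e3 cells/L, hence 1e9.
_FMOL_FACTOR = 1e9

CELL_STATISTICS = ("half_delta", "mean", "start", "log_mean")


def _cell_stat(n0: float, n1: float, how: str) -> float:
    if how == "half_delta":
        return (n1 - n0) / 2.0
    if how == "mean":
        return (n0 + n1) / 2.0
    if how == "start":
        return n0
    if how == "log_mean":
        if n0 <= 0 or n1 <= 0 or n0 == n1:
            return (n0 + n1) / 2.0
        return (n1 - n0) / math.log(n1 / n0)
    raise ValueError(f"unknown cell statistic {how!r}; use one of {CELL_STATISTICS}")


def _acceptor_S(tp: TimePoint, ds: ExperimentDataset) -> float | None:
    concs = [tp.pool(s) for s in ds.acceptor_species]
    if any(p is None for p in concs):
        return None
    return sum(p.conc for p in concs)


def _product_S(tp: TimePoint) -> float | None:
    p = tp.pool("sulfide")
    return None if p is None else p.conc


def cs_rate(
    ds: ExperimentDataset,
    basis: str = "acceptor",
    cell_stat: str = "half_delta",
    per_molecule: bool = False,
) -> pd.DataFrame:
    """Per-interval cell-specific reduction rates (fmol S cell⁻¹ day⁻¹).

    Parameters
    ----------
    basis
        ``"acceptor"`` uses the decrease of the electron-acceptor pool;
        ``"product"`` uses the increase of sulfide.  For thiosulfate
        experiments the product basis tracks acceptor-S consumption under
        wholesale reduction and is the published convention.
    cell_stat
        Cell-density statistic for the interval (see module docstring).
    per_molecule
        Report per acceptor molecule instead of per S atom (divides
        thiosulfate rates by two; identity for single-S acceptors).

    Intervals with a non-positive cell statistic are skipped with a warning.
    """
    if len(ds.points) < 2:
        raise ValueError("need at least two time points")
    rows = []
    for a, b in zip(ds.points, ds.points[1:]):
        if basis == "acceptor":
            ca, cb = _acceptor_S(a, ds), _acceptor_S(b, ds)
            dconc = None if ca is None or cb is None else ca - cb
        elif basis == "product":
            ca, cb = _product_S(a), _product_S(b)
            dconc = None if ca is None or cb is None else cb - ca
        else:
            raise ValueError(f"basis must be 'acceptor' or 'product', got {basis!r}")
        if dconc is None:
            continue
        if per_molecule and ds.acceptor == "thiosulfate":
            dconc /= 2.0
        n_eff = _cell_stat(a.cells, b.cells, cell_stat)
        if n_eff <= 0:
            warnings.warn(
                f"interval {a.t}-{b.t} h skipped: cell statistic <= 0",
                stacklevel=2,
            )
            continue
        dt_days = (b.t - a.t) / 24.0
        rows.append(
            {
                "t_start": a.t,
                "t_end": b.t,
                "rate_fmol_cell_day": abs(dconc) / dt_days / n_eff * _FMOL_FACTOR,
            }
        )
    return pd.DataFrame(rows)


def fraction_consumed(
    ds: ExperimentDataset,
    t_index: int | None = None,
    basis: str = "product",
    product_species: str = "sulfide",
) -> float | np.ndarray:
    """Consumed fraction of the initial acceptor sulfur, in percent.

    Default (product basis): 100 · [product S]_t / [acceptor S]_0, which is
    how the packaged tables define their f columns.  ``basis="reactant"``
    uses 100 · (1 − [acceptor S]_t / [acceptor S]_0) instead.  With
    ``t_index=None`` an array over all time points is returned.
    """
    idx = range(len(ds.points)) if t_index is None else [t_index]
    out = []
    for i in idx:
        tp = ds.points[i]
        if basis == "product":
            p = tp.pool(product_species)
            if p is None:
                raise ValueError(f"no {product_species} pool at t={tp.t}")
            frac = 100.0 * p.conc / ds.initial_acceptor_S
        elif basis == "reactant":
            acc = _acceptor_S(tp, ds)
            if acc is None:
                raise ValueError(f"acceptor pool missing at t={tp.t}")
            frac = 100.0 * (1.0 - acc / ds.initial_acceptor_S)
        else:
            raise ValueError(f"basis must be 'product' or 'reactant', got {basis!r}")
        if frac < -1e-9:
            raise ValueError(
                f"negative consumed fraction at t={tp.t}: inconsistent data"
            )
        out.append(max(frac, 0.0))
    return out[0] if t_index is not None else np.asarray(out)
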