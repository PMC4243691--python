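"""Elemental and isotopic mass-balance closure across measured pools.

In a closed batch culture the total sulfur inventory — and its isotope
composition — must be constant.  Residuals against the t = 0 inventory
quantify how well the measured pools close mass balance; the reporting
convention is (later − initial) in concentration, δ³⁴S and
Δ³³S.  Isotope residuals are always computed by mixing in ratio space and
converting to Δ³³S only at the end: Δ³³S is not conserved under linear
averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    EmptyMixtureError,
    IsotopeComposition,
    SulfurPool,
    mix,
)

__all__ = [
    "TimePoint",
    "ExperimentDataset",
    "TotalSulfur",
    "total_sulfur",
    "residuals",
    "bulk_from_sites",
    "thiosulfate_site_split",
]


@dataclass(frozen=True)
class TimePoint:
    """All pools measured in one sampling of a batch experiment."""

    t: float
    cells: float = 0.0
    cells_rsd: float | None = None
    pools: tuple[SulfurPool, ...] = ()
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError(f"time must be >= 0 (got {self.t})")
        if self.cells < 0:
            raise ValueError(f"cell density must be >= 0 (got {self.cells})")
        names = [p.species for p in self.pools]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate pool species in time point: {names}")

    def pool(self, species: str) -> SulfurPool | None:
        for p in self.pools:
            if p.species == species:
                return p
        return None


@dataclass(frozen=True)
class ExperimentDataset:
    """A batch reduction experiment: design, ordered time points, controls."""

    acceptor: str
    donor: str
    initial_acceptor_S: float
    points: tuple[TimePoint, ...]
    controls: tuple[TimePoint, ...] = ()
    experiment_id: str = ""
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.acceptor not in ("sulfate", "sulfite", "thiosulfate"):
            raise ValueError(f"unknown acceptor {self.acceptor!r}")
        if self.initial_acceptor_S <= 0:
            raise ValueError("initial_acceptor_S must be positive")
        ts = [tp.t for tp in self.points]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError(f"time points must be strictly increasing: {ts}")

    @property
    def acceptor_species(self) -> tuple[str, ...]:
        if self.acceptor == "thiosulfate":
            return ("thiosulfate_sulfonate", "thiosulfate_sulfane")
        return (self.acceptor,)


@dataclass(frozen=True)
class TotalSulfur:
    """Total S of a time point with the ratio-space mixed composition.

    ``isotope_coverage`` is the fraction of the summed sulfur carried by
    pools with a measured composition; if pools holding more than 5% of the
    sulfur lack compositions, ``warning`` is set (never raised).
    """

    conc: float
    comp: IsotopeComposition | None
    isotope_coverage: float
    warning: str | None = None

    def as_pool(self) -> SulfurPool:
        return SulfurPool("total", self.conc, None, self.comp)


def total_sulfur(tp: TimePoint) -> TotalSulfur:
    """Sum all pools of a time point; composition by ratio-space mixing.

    Pools without isotope measurements count toward the elemental total but
    are excluded from the isotopic mixture.
    """
    if not tp.pools:
        raise ValueError("time point has no pools")
    total = sum(p.conc for p in tp.pools)
    with_comp = [p for p in tp.pools if p.comp is not None and p.conc > 0]
    covered = sum(p.conc for p in with_comp)
    coverage = covered / total if total > 0 else 0.0
    warning = None
    if total > 0 and coverage < 0.95:
        missing = [p.species for p in tp.pools if p.comp is None and p.conc > 0]
        warning = (
            f"pools {missing} hold {100 * (1 - coverage):.1f}% of S without "
            "isotope measurements"
        )
    comp = None
    if with_comp:
        try:
            comp = mix(with_comp).comp
        except EmptyMixtureError:
            comp = None
    return TotalSulfur(total, comp, coverage, warning)


def residuals(ds: ExperimentDataset) -> pd.DataFrame:
    """Per-time-point mass and isotope imbalance against the t = 0 inventory.

    Columns: ``t``, ``dmass_mM`` (total S minus initial total S),
    ``dmass_pct`` (same, % of initial), ``dd34S_permil`` and
    ``dD33S_permil`` (mixed-total composition minus the t = 0 mixed total;
    sign convention later − initial), ``isotope_coverage``, ``warning``.
    """
    if not ds.points or ds.points[0].t != 0.0:
        raise ValueError("dataset must include a t = 0 reference time point")
    ref = total_sulfur(ds.points[0])
    rows = []
    for tp in ds.points:
        tot = total_sulfur(tp)
        d34 = dD33 = np.nan
        if tot.comp is not None and ref.comp is not None:
            d34 = tot.comp.delta34 - ref.comp.delta34
            dD33 = tot.comp.capdelta33 - ref.comp.capdelta33
        rows.append(
            {
                "t": tp.t,
                "dmass_mM": tot.conc - ref.conc,
                "dmass_pct": 100.0 * (tot.conc - ref.conc) / ref.conc,
                "dd34S_permil": d34,
                "dD33S_permil": dD33,
                "isotope_coverage": tot.isotope_coverage,
                "warning": tot.warning,
            }
        )
    return pd.DataFrame(rows)


def bulk_from_sites(
    sulfonate: SulfurPool, sulfane: SulfurPool, rtol: float = 1e-6
) -> SulfurPool:
    """Bulk thiosulfate from its two site pools (equal moles, ratio-space mix)."""
    if sulfonate.species != "thiosulfate_sulfonate":
        raise ValueError(f"expected sulfonate pool, got {sulfonate.species}")
    if sulfane.species != "thiosulfate_sulfane":
        raise ValueError(f"expected sulfane pool, got {sulfane.species}")
    if sulfonate.conc > 0 and abs(sulfonate.conc - sulfane.conc) > rtol * sulfonate.conc:
        raise ValueError(
            "thiosulfate sites must carry equal moles "
            f"({sulfonate.conc} vs {sulfane.conc} mM S)"
        )
    return mix([sulfonate, sulfane])


def thiosulfate_site_split(
    bulk_conc: float,
    sulfonate_comp: IsotopeComposition,
    sulfane_comp: IsotopeComposition,
) -> tuple[SulfurPool, SulfurPool]:
    """Split a bulk thiosulfate S inventory into its two equal-mole sites.

    Site compositions must be supplied: the split is bookkeeping, not an
    inference.  ``bulk_conc`` is in mM of total thiosulfate sulfur.
    """
    if bulk_conc < 0:
        raise ValueError("bulk concentration must be >= 0")
    half = bulk_conc / 2.0
    return (
        SulfurPool("thiosulfate_sulfonate", half, None, sulfonate_comp),
        SulfurPool("thiosulfate_sulfane", half, None, sulfane_comp),
    )
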