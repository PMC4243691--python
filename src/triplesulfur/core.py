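"""Triple sulfur isotope algebra.

Delta/ratio conversions, the mass-dependent reference line, fractionation
factors and exact ratio-space mixing.

Notation
--------
All delta values are in permil (‰).  A composition carries two deltas,

    δ³⁴S = 1000 · (³⁴R_sample / ³⁴R_ref − 1),   ³⁴R = ³⁴S/³²S,
    δ³³S = 1000 · (³³R_sample / ³³R_ref − 1),   ³³R = ³³S/³²S,

against a named reference frame.  The capital-delta value

    Δ³³S = δ³³S − 1000 · ((1 + δ³⁴S/1000)^0.515 − 1)

measures the deviation of the minor isotope from the mass-dependent
reference line with exponent 0.515.  Between two pools the triple-isotope
exponent is λ = ln(³³α)/ln(³⁴α), and ³⁴ε = (³⁴α − 1)·1000.

Mixing is computed on isotope ratios (mole-count bookkeeping), never by
averaging deltas or Δ³³S: mixing is non-linear in those coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "LAMBDA_REF",
    "R34_REF",
    "R33_REF",
    "SPECIES",
    "MEASURED_SPECIES",
    "FRAME_EXPERIMENT",
    "FRAME_VCDT",
    "IsotopeComposition",
    "FractionationFactor",
    "SulfurPool",
    "UndefinedLambdaError",
    "EmptyMixtureError",
    "capdelta33",
    "delta33_from_capdelta",
    "lambda_between",
    "mix",
    "shift_frame",
]

#: Exponent of the mass-dependent reference line used for Δ³³S.
LAMBDA_REF = 0.515

#: Absolute ³⁴S/³²S and ³³S/³²S ratios of the CDT reference.  They enter only
#: as mole-fraction weights in ratio-space mixing; results are insensitive to
#: their absolute scale (property-tested).
R34_REF = 0.0441626
R33_REF = 0.0078773

FRAME_EXPERIMENT = "experiment-initial"
FRAME_VCDT = "VCDT"

#: Measurable sulfur pools.  Thiosulfate is always represented by its two
#: structurally distinct sites (sulfonate S⁵⁺ and sulfane S⁰⁻¹), in equal
#: molar amounts, never as a single bulk pool.
MEASURED_SPECIES = (
    "sulfate",
    "sulfite",
    "sulfide",
    "thiosulfate_sulfonate",
    "thiosulfate_sulfane",
    "elemental_S",
)

#: All recognised pool labels; the last two are derived (mixtures), never
#: stored in datasets.
SPECIES = MEASURED_SPECIES + ("thiosulfate_bulk", "total")


class UndefinedLambdaError(ValueError):
    """λ requested between pools with identical δ³⁴S (ln ³⁴α = 0)."""


class EmptyMixtureError(ValueError):
    """Mixture requested over pools carrying no sulfur."""


def _check_delta(value: float, name: str, allow_nan: bool = False) -> None:
    if allow_nan and math.isnan(value):
        return
    if not value > -1000.0:
        raise ValueError(f"{name} must exceed -1000 permil (got {value})")


@dataclass(frozen=True)
class IsotopeComposition:
    """A (δ³³S, δ³⁴S) pair in permil against a named reference frame.

    Δ³³S is always derived from the stored deltas, never stored redundantly.
    """

    delta34: float
    delta33: float
    frame: str = FRAME_EXPERIMENT

    def __post_init__(self) -> None:
        # delta33 may be NaN: δ³³S unmeasured (δ³⁴S-only data); operations
        # needing the minor isotope reject or propagate it explicitly
        _check_delta(self.delta34, "delta34")
        _check_delta(self.delta33, "delta33", allow_nan=True)

    @classmethod
    def from_capdelta(
        cls, delta34: float, capdelta33: float, frame: str = FRAME_EXPERIMENT
    ) -> "IsotopeComposition":
        """Build a composition from (δ³⁴S, Δ³³S), the printed-table form."""
        return cls(delta34, delta33_from_capdelta(delta34, capdelta33), frame)

    @property
    def capdelta33(self) -> float:
        return capdelta33(self)

    def ratios(self) -> tuple[float, float]:
        """Absolute (³³R, ³⁴R) on the reference scale of :data:`R33_REF`/:data:`R34_REF`."""
        return (
            (1.0 + self.delta33 / 1000.0) * R33_REF,
            (1.0 + self.delta34 / 1000.0) * R34_REF,
        )

    @classmethod
    def from_ratios(
        cls, r33: float, r34: float, frame: str = FRAME_EXPERIMENT
    ) -> "IsotopeComposition":
        return cls(
            1000.0 * (r34 / R34_REF - 1.0),
            1000.0 * (r33 / R33_REF - 1.0),
            frame,
        )


def capdelta33(comp: IsotopeComposition) -> float:
    """Δ³³S of a composition: deviation from the 0.515 reference line (‰)."""
    return comp.delta33 - 1000.0 * (
        (1.0 + comp.delta34 / 1000.0) ** LAMBDA_REF - 1.0
    )


def delta33_from_capdelta(delta34: float, capdelta33: float) -> float:
    """Inverse of :func:`capdelta33`: δ³³S implied by (δ³⁴S, Δ³³S)."""
    _check_delta(delta34, "delta34")
    return capdelta33 + 1000.0 * ((1.0 + delta34 / 1000.0) ** LAMBDA_REF - 1.0)


@dataclass(frozen=True)
class FractionationFactor:
    """A (³⁴α, ³³λ) pair with optional 1σ uncertainties.

    ³⁴ε = (³⁴α − 1)·1000 and ³³α = ³⁴α^³³λ are derived on demand.
    """

    alpha34: float
    lambda33: float = LAMBDA_REF
    sd_alpha34: float | None = None
    sd_lambda33: float | None = None

    def __post_init__(self) -> None:
        if not self.alpha34 > 0:
            raise ValueError(f"alpha34 must be positive (got {self.alpha34})")

    @classmethod
    def from_epsilon(
        cls,
        epsilon34: float,
        lambda33: float = LAMBDA_REF,
        sd_epsilon34: float | None = None,
        sd_lambda33: float | None = None,
    ) -> "FractionationFactor":
        sd_a = None if sd_epsilon34 is None else sd_epsilon34 / 1000.0
        return cls(1.0 + epsilon34 / 1000.0, lambda33, sd_a, sd_lambda33)

    @property
    def epsilon34(self) -> float:
        return (self.alpha34 - 1.0) * 1000.0

    @property
    def sd_epsilon34(self) -> float | None:
        return None if self.sd_alpha34 is None else self.sd_alpha34 * 1000.0

    @property
    def alpha33(self) -> float:
        return self.alpha34 ** self.lambda33

    def alpha(self, isotope: int) -> float:
        """³⁴α or ³³α for ``isotope`` in {33, 34}."""
        if isotope == 34:
            return self.alpha34
        if isotope == 33:
            return self.alpha33
        raise ValueError(f"isotope must be 33 or 34 (got {isotope})")


@dataclass(frozen=True)
class SulfurPool:
    """One chemical pool: concentration in mM of sulfur atoms plus composition.

    ``comp`` is ``None`` for pools whose isotopes were not measured.
    """

    species: str
    conc: float
    sd_conc: float | None = None
    comp: IsotopeComposition | None = None

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(
                f"unknown species {self.species!r}; expected one of {SPECIES}"
            )
        if self.conc < 0:
            raise ValueError(f"concentration must be >= 0 (got {self.conc})")


def lambda_between(a: IsotopeComposition, b: IsotopeComposition) -> float:
    """Triple-isotope exponent λ = ln(³³α)/ln(³⁴α) between two compositions.

    λ is invariant under a common change of reference frame, so the two
    compositions may be expressed on any shared frame.
    """
    if math.isnan(a.delta33) or math.isnan(b.delta33):
        raise ValueError("lambda requires measured delta33 on both pools")
    ln_a34 = math.log((1000.0 + a.delta34) / (1000.0 + b.delta34))
    if ln_a34 == 0.0:
        raise UndefinedLambdaError(
            "lambda is undefined for pools with identical delta34"
        )
    ln_a33 = math.log((1000.0 + a.delta33) / (1000.0 + b.delta33))
    return ln_a33 / ln_a34


def mix(pools: list[SulfurPool]) -> SulfurPool:
    """Concentration-weighted mixture of pools, exact in ratio space.

    Isotopologue mole counts are summed directly: each mM of sulfur in a pool
    with ratios (³³R, ³⁴R) carries a ³²S mole fraction 1/(1 + ³³R + ³⁴R).
    Total moles of each isotope are conserved exactly.  Pools without a
    measured composition are rejected; filter them out first (see
    ``mass_balance.total_sulfur`` for the tolerant variant).
    """
    active = [p for p in pools if p.conc > 0]
    if not active:
        raise EmptyMixtureError("all pool concentrations are zero")
    frames = {p.comp.frame for p in active if p.comp is not None}
    if len(frames) > 1:
        raise ValueError(f"cannot mix compositions on different frames: {frames}")
    if any(p.comp is None for p in active):
        raise ValueError("cannot mix pools lacking isotope compositions")

    n32 = n33 = n34 = 0.0
    for p in active:
        r33, r34 = p.comp.ratios()
        # pools with unmeasured δ³³S poison only the minor-isotope channel;
        # their ³²S weight uses the reference-line δ³³S (negligible effect)
        r33_w = r33
        if math.isnan(r33):
            r33_w = (1.0 + delta33_from_capdelta(p.comp.delta34, 0.0) / 1000.0) * R33_REF
        p32 = p.conc / (1.0 + r33_w + r34)
        n32 += p32
        n33 += p32 * r33
        n34 += p32 * r34
    d33 = 1000.0 * (n33 / n32 / R33_REF - 1.0)
    comp = IsotopeComposition(
        1000.0 * (n34 / n32 / R34_REF - 1.0), d33, active[0].comp.frame
    )
    total = sum(p.conc for p in active)
    names = {p.species for p in active}
    species = active[0].species if len(names) == 1 else "total"
    if names == {"thiosulfate_sulfonate", "thiosulfate_sulfane"}:
        species = "thiosulfate_bulk"
    return SulfurPool(species, total, None, comp)


def shift_frame(
    comp: IsotopeComposition, frame_origin: IsotopeComposition, new_frame: str
) -> IsotopeComposition:
    """Re-express ``comp`` on the frame on which ``frame_origin`` is given.

    ``frame_origin`` is the composition of the current frame's reference
    material expressed on the target frame (e.g. the experiment-initial total
    sulfur on VCDT).  The conversion is a multiplication of ratios and is
    invertible to numerical precision.
    """
    if frame_origin.frame != new_frame:
        raise ValueError("frame_origin must be expressed on the target frame")
    d34 = ((1.0 + comp.delta34 / 1000.0) * (1.0 + frame_origin.delta34 / 1000.0) - 1.0)
    d33 = ((1.0 + comp.delta33 / 1000.0) * (1.0 + frame_origin.delta33 / 1000.0) - 1.0)
    return IsotopeComposition(d34 * 1000.0, d33 * 1000.0, new_frame)
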