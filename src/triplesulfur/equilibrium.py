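"""Equilibrium sulfur isotope fractionation from vibrational frequencies.

The reduced partition function ratio (β-factor) of a ³⁴S/³²S isotopologue
pair follows Bigeleisen–Mayer/Urey theory in the harmonic approximation:

    β = σ · Π_modes (u_h/u_l) · exp((u_l − u_h)/2) · (1 − e^(−u_l))/(1 − e^(−u_h)),

with u = h·c·ν̃/(k_B·T) and σ the symmetry-number ratio (unity for single
substitution).  Differences of 1000·ln β between two species give the
equilibrium fractionation 1000·ln ³⁴α at each temperature.

Frequencies are consumed from small text fixtures (one species per file;
see :func:`read_frequency_set`).  Harmonic frequencies from electronic-
structure methods systematically overestimate fundamentals; a uniform
scaling factor (0.8928 for HF/6-31G*) corrects this and is applied through
:func:`scale_frequencies` or the set's ``scale`` field.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import constants

__all__ = [
    "FrequencySet",
    "HF_SCALING",
    "scale_frequencies",
    "beta_factor",
    "equilibrium_epsilon",
    "read_frequency_set",
    "write_frequency_set",
    "load_packaged_frequency_set",
    "PACKAGED_SPECIES",
]

#: Least-squares frequency scaling factor for HF/6-31G* harmonic frequencies.
HF_SCALING = 0.8928

#: hc/k_B in cm·K: converts a wavenumber in cm⁻¹ at temperature T to u = C·ν̃/T.
_HC_OVER_KB = constants.h * constants.c * 100.0 / constants.k

#: Species with packaged frequency fixtures (synthetic, model-derived; see
#: ``triplesulfur.modes``).
PACKAGED_SPECIES = (
    "sulfide",
    "sulfite",
    "sulfate",
    "thiosulfate_sulfonate",
    "thiosulfate_sulfane",
)


@dataclass(frozen=True)
class FrequencySet:
    """Vibrational frequencies (cm⁻¹) of a ³²S/³⁴S isotopologue pair."""

    name: str
    freqs_light: tuple[float, ...]
    freqs_heavy: tuple[float, ...]
    symmetry_ratio: float = 1.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if len(self.freqs_light) != len(self.freqs_heavy):
            raise ValueError("light and heavy isotopologues need equal mode counts")
        if any(f <= 0 for f in self.freqs_light + self.freqs_heavy):
            raise ValueError("all frequencies must be positive")
        for fl, fh in zip(self.freqs_light, self.freqs_heavy):
            if fh > fl * (1.0 + 1e-6):
                raise ValueError(
                    f"heavy-isotopologue mode {fh} cm-1 exceeds light mode {fl}"
                )


def scale_frequencies(fs: FrequencySet, factor: float = HF_SCALING) -> FrequencySet:
    """Multiply every mode of both isotopologues by ``factor``."""
    if factor <= 0:
        raise ValueError(f"scaling factor must be positive (got {factor})")
    return replace(
        fs,
        freqs_light=tuple(f * factor for f in fs.freqs_light),
        freqs_heavy=tuple(f * factor for f in fs.freqs_heavy),
        scale=fs.scale * factor,
    )


def beta_factor(fs: FrequencySet, T: float, log: bool = False) -> float:
    """β (or 1000·ln β with ``log=True``) of a frequency set at T kelvin.

    The ``scale`` field of the set has already been applied to the stored
    frequencies by the reader/scaler, so modes are used as given.
    """
    if T <= 0:
        raise ValueError(f"temperature must be positive (got {T} K)")
    ln_beta = math.log(fs.symmetry_ratio)
    for fl, fh in zip(fs.freqs_light, fs.freqs_heavy):
        ul = _HC_OVER_KB * fl / T
        uh = _HC_OVER_KB * fh / T
        ln_beta += (
            math.log(uh / ul)
            + (ul - uh) / 2.0
            + math.log(math.expm1(ul)) - ul
            - (math.log(math.expm1(uh)) - uh)
        )
    return 1000.0 * ln_beta if log else math.exp(ln_beta)


def equilibrium_epsilon(a: FrequencySet, b: FrequencySet, T) -> float | pd.DataFrame:
    """1000·ln ³⁴α between species ``a`` and ``b`` at temperature(s) ``T`` (K).

    Scalar T returns a float; an array returns a DataFrame with ``T_K``,
    ``T_C`` and ``eps_permil`` columns.  Comparing sets with different
    frequency scalings is almost certainly unintended and triggers a
    warning (the value is still computed).
    """
    if abs(a.scale - b.scale) > 1e-9:
        warnings.warn(
            f"frequency scalings differ ({a.scale} vs {b.scale}); "
            "the fractionation mixes inconsistent harmonic corrections",
            stacklevel=2,
        )
    Ts = np.atleast_1d(np.asarray(T, dtype=float))
    eps = np.array(
        [beta_factor(a, t, log=True) - beta_factor(b, t, log=True) for t in Ts]
    )
    if np.isscalar(T) or np.ndim(T) == 0:
        return float(eps[0])
    return pd.DataFrame({"T_K": Ts, "T_C": Ts - 273.15, "eps_permil": eps})


# ---------------------------------------------------------------------------
# text format: header lines then one "nu_light nu_heavy" pair per mode

def read_frequency_set(source) -> FrequencySet:
    """Read the one-species frequency text format.

    Lines starting with ``#`` are comments.  Header keys ``name``,
    ``symmetry_ratio`` and ``scale`` appear as ``key: value`` lines before
    the mode list; each mode line holds ``nu_light nu_heavy`` in cm⁻¹.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    name, sym, scale = "", 1.0, 1.0
    light, heavy = [], []
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" in line:
            key, _, val = line.partition(":")
            key = key.strip().lower()
            if key == "name":
                name = val.strip()
            elif key == "symmetry_ratio":
                sym = float(val)
            elif key == "scale":
                scale = float(val)
            else:
                raise ValueError(f"line {ln}: unknown header key {key!r}")
        else:
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"line {ln}: expected 'nu_light nu_heavy'")
            light.append(float(parts[0]))
            heavy.append(float(parts[1]))
    if not light:
        raise ValueError("no vibrational modes found")
    fs = FrequencySet(name, tuple(light), tuple(heavy), sym, 1.0)
    if scale != 1.0:
        fs = scale_frequencies(fs, scale)
    return fs


def write_frequency_set(fs: FrequencySet, path) -> None:
    buf = io.StringIO()
    buf.write("# synthetic frequency set: classical harmonic point-mass model\n")
    buf.write("# (triplesulfur.modes), NOT electronic-structure output\n")
    buf.write(f"name: {fs.name}\n")
    buf.write(f"symmetry_ratio: {fs.symmetry_ratio:g}\n")
    buf.write("scale: 1\n")  # stored frequencies already carry any scaling
    for fl, fh in zip(fs.freqs_light, fs.freqs_heavy):
        buf.write(f"{fl:.4f} {fh:.4f}\n")
    Path(path).write_text(buf.getvalue())


def load_packaged_frequency_set(species: str) -> FrequencySet:
    """Load a packaged synthetic frequency fixture by species name."""
    from importlib.resources import files

    if species not in PACKAGED_SPECIES:
        raise ValueError(
            f"no packaged frequency set for {species!r}; "
            f"available: {PACKAGED_SPECIES}"
        )
    res = files("triplesulfur").joinpath("data", f"frequencies_synthetic_{species}.txt")
    return read_frequency_set(io.StringIO(res.read_text()))
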