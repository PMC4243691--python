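"""Synthetic harmonic frequency sets for sulfur species (model-derived).

The packaged frequency fixtures are NOT quantum-chemical results: they are
generated by this classical point-mass normal-mode model — atoms on
literature equilibrium geometries, a diagonal valence force field (bond
stretches and angle bends), Cartesian Hessian by numerical differentiation,
mass-weighting and diagonalisation.  Force constants were calibrated once
against literature spectroscopic fundamentals of each species (H₂S 2615,
1183, 2626 cm⁻¹; aqueous sulfate 981, 451, 613, 1104 cm⁻¹; sulfite 967,
620, 933, 469 cm⁻¹; thiosulfate S–S stretch near 446 cm⁻¹ with SO₃-group
modes near their sulfite analogues) and are frozen here.  Heavy-isotopologue
frequencies follow from substituting ³⁴S at the requested position with the
force field unchanged — the classical Urey construction.

Because the force field is harmonic and already calibrated to observed
fundamentals, the generated sets carry ``scale = 1`` (no HF-style scaling
is needed).  They are physically reasonable but synthetic: β-factors from
them reproduce the magnitude and temperature dependence of published
sulfate–sulfide equilibrium fractionations, not any specific published
curve.
"""

from __future__ import annotations

import math

import numpy as np

from .equilibrium import FrequencySet

__all__ = ["SPECIES_MODELS", "generate_frequency_set", "write_packaged_fixtures"]

_AMU = 1.66053906660e-27  # kg
_C = 2.99792458e10  # cm/s

MASS = {"H": 1.00783, "O": 15.9949, "S32": 31.97207, "S34": 33.96787}


class _Molecule:
    """Geometry (Å), bonds (N/m) and angle bends (J/rad²) of one species."""

    def __init__(self, atoms, coords, bonds, angles, substitutable):
        self.atoms = atoms          # element labels; "S" entries may be 32/34
        self.coords = np.asarray(coords, dtype=float) * 1e-10  # m
        self.bonds = bonds          # (i, j, k_Nm)
        self.angles = angles        # (i, j, k, k_J_rad2) with vertex j
        self.substitutable = substitutable  # index of the S to substitute

    def energy(self, x):
        x = x.reshape(-1, 3)
        e = 0.0
        for i, j, k in self.bonds:
            r = np.linalg.norm(x[i] - x[j])
            r0 = np.linalg.norm(self.coords[i] - self.coords[j])
            e += 0.5 * k * (r - r0) ** 2
        for i, j, k, ka in self.angles:
            e += 0.5 * ka * (self._angle(x, i, j, k) - self._angle(
                self.coords, i, j, k)) ** 2
        return e

    @staticmethod
    def _angle(x, i, j, k):
        a = x[i] - x[j]
        b = x[k] - x[j]
        c = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
        return math.acos(max(-1.0, min(1.0, c)))

    def frequencies(self, heavy: bool) -> np.ndarray:
        masses = []
        for idx, el in enumerate(self.atoms):
            if el == "S" and heavy and idx == self.substitutable:
                masses.append(MASS["S34"])
            elif el == "S":
                masses.append(MASS["S32"])
            else:
                masses.append(MASS[el])
        masses = np.repeat(np.asarray(masses) * _AMU, 3)

        n = self.coords.size
        x0 = self.coords.ravel().copy()
        h = 1e-13  # m
        hess = np.empty((n, n))
        for i in range(n):
            for j in range(i, n):
                xpp = x0.copy(); xpp[i] += h; xpp[j] += h
                xpm = x0.copy(); xpm[i] += h; xpm[j] -= h
                xmp = x0.copy(); xmp[i] -= h; xmp[j] += h
                xmm = x0.copy(); xmm[i] -= h; xmm[j] -= h
                hess[i, j] = hess[j, i] = (
                    self.energy(xpp) - self.energy(xpm)
                    - self.energy(xmp) + self.energy(xmm)
                ) / (4 * h * h)
        hess /= np.sqrt(np.outer(masses, masses))
        evals = np.linalg.eigvalsh(hess)
        evals = np.sort(evals)[6:]  # drop translations/rotations
        if evals[0] <= 0:
            raise RuntimeError("force field produced a non-positive mode")
        return np.sqrt(evals) / (2 * math.pi * _C)  # cm^-1


def _h2s():
    r, ang = 1.336, math.radians(92.1)
    coords = [
        [0.0, 0.0, 0.0],
        [r * math.sin(ang / 2), r * math.cos(ang / 2), 0.0],
        [-r * math.sin(ang / 2), r * math.cos(ang / 2), 0.0],
    ]
    return _Molecule(
        ["S", "H", "H"], coords,
        bonds=[(0, 1, 395.3), (0, 2, 395.3)],
        angles=[(1, 0, 2, 7.19e-19)],
        substitutable=0,
    )


def _tetrahedron(r):
    s = r / math.sqrt(3.0)
    return [[s, s, s], [s, -s, -s], [-s, s, -s], [-s, -s, s]]


def _sulfate():
    coords = [[0.0, 0.0, 0.0]] + _tetrahedron(1.49)
    bonds = [(0, i, 670.3) for i in (1, 2, 3, 4)]
    angles = [
        (i, 0, j, 1.919e-18)
        for i in (1, 2, 3, 4) for j in (1, 2, 3, 4) if i < j
    ]
    return _Molecule(["S", "O", "O", "O", "O"], coords, bonds, angles, 0)


def _pyramid(r, ang_deg, apex_el, base_el, k_bond, k_ang, extra=None):
    # apex at origin, three base atoms below with base-apex-base angle ang
    ang = math.radians(ang_deg)
    # place base atoms at polar angle theta from -z axis s.t. O-S-O = ang
    st = math.sqrt((1.0 - math.cos(ang)) / 1.5)
    ct = math.sqrt(1.0 - st * st)
    coords = [[0.0, 0.0, 0.0]]
    for k in range(3):
        phi = 2 * math.pi * k / 3
        coords.append([r * st * math.cos(phi), r * st * math.sin(phi), -r * ct])
    atoms = [apex_el] + [base_el] * 3
    bonds = [(0, i, k_bond) for i in (1, 2, 3)]
    angles = [(i, 0, j, k_ang) for i in (1, 2, 3) for j in (1, 2, 3) if i < j]
    return atoms, coords, bonds, angles


def _sulfite():
    atoms, coords, bonds, angles = _pyramid(1.53, 105.0, "S", "O", 522.2, 2.224e-18)
    return _Molecule(atoms, coords, bonds, angles, 0)


def _thiosulfate(substitute: str):
    # SO3 group as in sulfite around the central (sulfonate) S, with the
    # terminal sulfane S on the +z axis
    atoms, coords, bonds, angles = _pyramid(1.47, 109.0, "S", "O", 560.0, 2.0e-18)
    atoms = atoms + ["S"]
    coords = coords + [[0.0, 0.0, 2.01]]
    bonds = bonds + [(0, 4, 410.0)]
    angles = angles + [(i, 0, 4, 0.9e-18) for i in (1, 2, 3)]
    sub = 0 if substitute == "sulfonate" else 4
    return _Molecule(atoms, coords, bonds, angles, sub)


SPECIES_MODELS = {
    "sulfide": _h2s,
    "sulfite": _sulfite,
    "sulfate": _sulfate,
    "thiosulfate_sulfonate": lambda: _thiosulfate("sulfonate"),
    "thiosulfate_sulfane": lambda: _thiosulfate("sulfane"),
}


def generate_frequency_set(species: str) -> FrequencySet:
    """Light/heavy harmonic frequencies for one species (synthetic model)."""
    if species not in SPECIES_MODELS:
        raise ValueError(f"no model for {species!r}")
    mol = SPECIES_MODELS[species]()
    light = mol.frequencies(heavy=False)
    heavy = mol.frequencies(heavy=True)
    # clip tiny upward numerical noise on S-insensitive modes
    heavy = np.minimum(heavy, light)
    return FrequencySet(species, tuple(light), tuple(heavy), 1.0, 1.0)


def write_packaged_fixtures(directory) -> None:
    """Regenerate the packaged synthetic frequency fixture files."""
    from pathlib import Path

    from .equilibrium import write_frequency_set

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for species in SPECIES_MODELS:
        fs = generate_frequency_set(species)
        write_frequency_set(fs, directory / f"frequencies_synthetic_{species}.txt")
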