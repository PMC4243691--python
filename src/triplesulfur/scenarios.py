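"""Forward models of candidate reduction pathways and scenario scoring.

A scenario is a set of sulfur-transferring transformations (source pool →
product branches with S-mole fractions and per-branch fractionation
factors) executed as an explicit forward-Euler distillation on a discrete
reaction-progress grid.  Isotopes are tracked as isotopologue mole counts,
so every trajectory conserves elemental and isotopic mass at machine
precision; recycling branches (product returned to a reactant pool) update
the reactant composition by exact mixing.

Thiosulfate reduction offers three limiting pathways: wholesale reduction
of both sites to sulfide (8 e⁻ per molecule), reduction of the sulfonate
site only (6 e⁻, sulfane left as elemental S), or of the sulfane site only
(2 e⁻, sulfonate released as sulfite).  Sulfite reduction scenarios cover
stepwise reduction through trithionate (implicit, zero residence time),
thiosulfate as the sole intermediate (with or without sulfonate recycling)
and parallel independent reductions to sulfide and thiosulfate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .core import (
    LAMBDA_REF,
    IsotopeComposition,
    SulfurPool,
    mix,
)
from .mass_balance import ExperimentDataset, bulk_from_sites

__all__ = [
    "Branch",
    "Transformation",
    "ScenarioSpec",
    "ScenarioPrediction",
    "ScenarioError",
    "simulate_scenario",
    "score_scenarios",
    "site_specific_offsets",
    "thio_wholesale",
    "thio_sulfonate_only",
    "thio_sulfane_only",
    "sulfite_trithionate_stepwise",
    "sulfite_thiosulfate_intermediate",
    "sulfite_parallel",
]

#: Nominal sulfur valence per pool, used to validate electron bookkeeping.
VALENCE = {
    "sulfate": 6,
    "sulfite": 4,
    "thiosulfate_sulfonate": 5,
    "thiosulfate_sulfane": -1,
    "elemental_S": 0,
    "sulfide": -2,
}
VALENCE["thiosulfate_bulk"] = 2  # equal-mole average of the two sites


class ScenarioError(ValueError):
    """Scenario specification does not conserve sulfur or electrons."""


@dataclass(frozen=True)
class Branch:
    """One product branch of a transformation.

    ``fraction`` is the share of transformed S moles routed to ``target``.
    The branch fractionation is α = (1 + ε/1000)·(1 + ε_offset/1000); the
    offset encodes a fixed upstream step (e.g. intermediate formation) so
    that ``epsilon34`` can remain the free parameter of a two-step chain.
    """

    target: str
    fraction: float
    epsilon34: float = 0.0
    lambda33: float = LAMBDA_REF
    epsilon34_offset: float = 0.0
    param: str | None = None  # name of a fitted parameter bound to epsilon34

    def alpha(self, isotope: int) -> float:
        a34 = (1.0 + self.epsilon34 / 1000.0) * (1.0 + self.epsilon34_offset / 1000.0)
        return a34 if isotope == 34 else a34 ** self.lambda33


@dataclass(frozen=True)
class Transformation:
    """Consumption of one source pool, split over product branches.

    ``rate`` is the relative consumption rate (mM S per unit reaction
    progress, normalised to the driving transformation).  Source
    ``thiosulfate_bulk`` consumes both sites in equal moles, fractionating
    each site with the same branch α (non-site-specific reduction).
    """

    source: str
    branches: tuple[Branch, ...]
    rate: float = 1.0
    electrons_per_S: float | None = None

    def __post_init__(self) -> None:
        total = sum(b.fraction for b in self.branches)
        if abs(total - 1.0) > 1e-9:
            raise ScenarioError(
                f"branch fractions of {self.source} sum to {total}, not 1: "
                "stoichiometry must conserve sulfur"
            )
        if self.electrons_per_S is not None:
            implied = sum(
                b.fraction * (VALENCE[self.source] - VALENCE[b.target])
                for b in self.branches
            )
            if abs(implied - self.electrons_per_S) > 1e-9:
                raise ScenarioError(
                    f"stated {self.electrons_per_S} e-/S for {self.source} but "
                    f"stoichiometry implies {implied}"
                )


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    transformations: tuple[Transformation, ...]
    #: pools whose initial S defines the acceptor inventory (normalises
    #: reaction progress: ξ = gross S through the transformations per unit
    #: progress equals one acceptor inventory)
    acceptor_species: tuple[str, ...] = ("sulfate",)
    #: electrons transferred per molecule of acceptor at unit progress
    electrons_per_molecule: float | None = None
    #: observable used to align dataset time points with the trajectory
    progress_basis: str = "product"
    notes: str = ""

    def free_params(self) -> list[str]:
        seen: list[str] = []
        for tr in self.transformations:
            for b in tr.branches:
                if b.param is not None and b.param not in seen:
                    seen.append(b.param)
        return seen

    def with_params(self, values: dict[str, float]) -> "ScenarioSpec":
        new_trs = []
        for tr in self.transformations:
            new_brs = tuple(
                replace(b, epsilon34=values[b.param]) if b.param in values else b
                for b in tr.branches
            )
            new_trs.append(replace(tr, branches=new_brs))
        return replace(self, transformations=tuple(new_trs))


@dataclass
class ScenarioPrediction:
    """Simulated trajectory (and, after scoring, the best-fit misfit)."""

    spec: ScenarioSpec
    trajectory: pd.DataFrame
    params: dict = field(default_factory=dict)
    rms: float | None = None


# ---------------------------------------------------------------------------
# simulation engine: isotopologue mole bookkeeping

def _pool_state(pool: SulfurPool) -> np.ndarray:
    comp = pool.comp or IsotopeComposition(0.0, 0.0)
    if math.isnan(comp.delta33):
        # forward models need a definite minor-isotope start; pools with
        # unmeasured δ³³S are placed on the mass-dependent reference line
        comp = IsotopeComposition.from_capdelta(comp.delta34, 0.0, comp.frame)
    r33, r34 = comp.ratios()
    n32 = pool.conc / (1.0 + r33 + r34)
    return np.array([n32, n32 * r33, n32 * r34])


def _state_delta(n: np.ndarray) -> tuple[float, float, float]:
    """(total mM S, δ³⁴S, δ³³S) of an isotopologue state vector."""
    total = n.sum()
    if n[0] <= 0.0:
        return total, np.nan, np.nan
    comp = IsotopeComposition.from_ratios(n[1] / n[0], n[2] / n[0])
    return total, comp.delta34, comp.delta33


def _parcel(n_src: np.ndarray, dm: float, alpha33: float, alpha34: float) -> np.ndarray:
    """Isotopologue moles of a parcel of dm (mM S) fractionated off n_src."""
    r33 = n_src[1] / n_src[0] * alpha33
    r34 = n_src[2] / n_src[0] * alpha34
    p32 = dm / (1.0 + r33 + r34)
    return np.array([p32, p32 * r33, p32 * r34])


def simulate_scenario(
    spec: ScenarioSpec,
    initial: dict[str, SulfurPool],
    consumed: float = 0.5,
    step: float = 0.001,
    record_every: int = 10,
) -> ScenarioPrediction:
    """Run a scenario forward to the requested consumed fraction.

    Parameters
    ----------
    initial
        Pools at t = 0, keyed by species.  The source of the first
        transformation defines the acceptor; its initial S normalises
        reaction progress.
    consumed
        Fraction of the initial acceptor S to push through the driving
        transformation (the reaction-progress endpoint).
    step
        Progress-grid step as a fraction of initial acceptor S.  Halving
        the default changes trajectories by less than 0.01‰.
    """
    state: dict[str, np.ndarray] = {
        sp: _pool_state(pool) for sp, pool in initial.items()
    }
    for tr in spec.transformations:
        sources = (
            ("thiosulfate_sulfonate", "thiosulfate_sulfane")
            if tr.source == "thiosulfate_bulk"
            else (tr.source,)
        )
        for sp in sources:
            state.setdefault(sp, np.zeros(3))
        for b in tr.branches:
            state.setdefault(b.target, np.zeros(3))

    for sp in spec.acceptor_species:
        state.setdefault(sp, np.zeros(3))
    s0 = sum(state[sp].sum() for sp in spec.acceptor_species)
    if s0 <= 0.0:
        raise ScenarioError(
            f"no initial acceptor sulfur in {spec.acceptor_species}"
        )

    n_steps = max(int(round(consumed / step)), 1)
    dxi = consumed / n_steps
    records = []

    def record(xi: float) -> None:
        row: dict[str, float] = {"progress": xi}
        for sp, n in state.items():
            total, d34, d33 = _state_delta(n)
            row[f"{sp}_mM"] = total
            row[f"{sp}_d34"] = d34
            row[f"{sp}_d33"] = d33
        records.append(row)

    record(0.0)
    for k in range(1, n_steps + 1):
        for tr in spec.transformations:
            dm = tr.rate * dxi * s0
            if tr.source == "thiosulfate_bulk":
                sources = [
                    ("thiosulfate_sulfonate", dm / 2.0),
                    ("thiosulfate_sulfane", dm / 2.0),
                ]
            else:
                sources = [(tr.source, dm)]
            for sp, amount in sources:
                avail = state[sp].sum()
                take = min(amount, avail)
                if take <= 0.0:
                    continue
                for b in tr.branches:
                    parcel = _parcel(
                        state[sp], take * b.fraction, b.alpha(33), b.alpha(34)
                    )
                    state[sp] = state[sp] - parcel
                    state[b.target] = state[b.target] + parcel
                if np.any(state[sp] < -1e-12):
                    raise ScenarioError(
                        f"{sp} driven below zero; reduce step or consumed"
                    )
        if k % record_every == 0 or k == n_steps:
            record(k * dxi)

    traj = pd.DataFrame(records)
    # derived bulk-thiosulfate columns where both sites exist
    if "thiosulfate_sulfonate_mM" in traj and "thiosulfate_sulfane_mM" in traj:
        pairs = []
        for _, row in traj.iterrows():
            conc = row["thiosulfate_sulfonate_mM"] + row["thiosulfate_sulfane_mM"]
            if conc > 0 and np.isfinite(row["thiosulfate_sulfonate_d34"]):
                son = SulfurPool(
                    "thiosulfate_sulfonate",
                    row["thiosulfate_sulfonate_mM"],
                    None,
                    IsotopeComposition(
                        row["thiosulfate_sulfonate_d34"],
                        row["thiosulfate_sulfonate_d33"],
                    ),
                )
                sane = SulfurPool(
                    "thiosulfate_sulfane",
                    row["thiosulfate_sulfane_mM"],
                    None,
                    IsotopeComposition(
                        row["thiosulfate_sulfane_d34"],
                        row["thiosulfate_sulfane_d33"],
                    ),
                )
                bulk = mix([son, sane])
                pairs.append((conc, bulk.comp.delta34, bulk.comp.delta33))
            else:
                pairs.append((conc, np.nan, np.nan))
        traj["thiosulfate_bulk_mM"] = [p[0] for p in pairs]
        traj["thiosulfate_bulk_d34"] = [p[1] for p in pairs]
        traj["thiosulfate_bulk_d33"] = [p[2] for p in pairs]
    return ScenarioPrediction(spec, traj)


# ---------------------------------------------------------------------------
# canonical scenario builders

def thio_wholesale(epsilon34: float = -7.1, lambda33: float = LAMBDA_REF) -> ScenarioSpec:
    """Non-site-specific (wholesale) thiosulfate reduction to sulfide, 8 e⁻."""
    return ScenarioSpec(
        "thio_wholesale",
        (
            Transformation(
                "thiosulfate_bulk",
                (Branch("sulfide", 1.0, epsilon34, lambda33, param="eps_red"),),
                electrons_per_S=4.0,
            ),
        ),
        acceptor_species=("thiosulfate_sulfonate", "thiosulfate_sulfane"),
        electrons_per_molecule=8.0,
        progress_basis="product",
    )


def thio_sulfonate_only(
    epsilon34: float = -8.0, lambda33: float = LAMBDA_REF
) -> ScenarioSpec:
    """Sulfonate-site reduction to sulfide; sulfane left behind as S⁰ (6 e⁻)."""
    return ScenarioSpec(
        "thio_sulfonate_only",
        (
            Transformation(
                "thiosulfate_sulfonate",
                (Branch("sulfide", 1.0, epsilon34, lambda33, param="eps_red"),),
                rate=0.5,
                electrons_per_S=7.0,
            ),
            Transformation(
                "thiosulfate_sulfane",
                (Branch("elemental_S", 1.0, 0.0, lambda33),),
                rate=0.5,
                electrons_per_S=-1.0,
            ),
        ),
        acceptor_species=("thiosulfate_sulfonate", "thiosulfate_sulfane"),
        electrons_per_molecule=6.0,
        progress_basis="product",
    )


def thio_sulfane_only(
    epsilon34: float = -5.0, lambda33: float = LAMBDA_REF
) -> ScenarioSpec:
    """Sulfane-site reduction to sulfide; sulfonate released as sulfite (2 e⁻)."""
    return ScenarioSpec(
        "thio_sulfane_only",
        (
            Transformation(
                "thiosulfate_sulfane",
                (Branch("sulfide", 1.0, epsilon34, lambda33, param="eps_red"),),
                rate=0.5,
                electrons_per_S=1.0,
            ),
            Transformation(
                "thiosulfate_sulfonate",
                (Branch("sulfite", 1.0, 0.0, lambda33),),
                rate=0.5,
                electrons_per_S=1.0,
            ),
        ),
        acceptor_species=("thiosulfate_sulfonate", "thiosulfate_sulfane"),
        electrons_per_molecule=2.0,
        progress_basis="product",
    )


def sulfite_parallel(
    epsilon_sulfide: float = -5.0,
    epsilon_sulfonate: float = 15.0,
    epsilon_sulfane: float = -15.0,
    thiosulfate_to_sulfide: float = 2.0,
    lambda33: float = LAMBDA_REF,
) -> ScenarioSpec:
    """Parallel, independent sulfite → sulfide and sulfite → thiosulfate.

    ``thiosulfate_to_sulfide`` is the S-mole branching ratio of thiosulfate
    to sulfide production (observed ≈ 2:1); the thiosulfate branch is split
    equally between its sites with large opposed site fractionations.
    """
    r = thiosulfate_to_sulfide
    phi_hs = 1.0 / (1.0 + r)
    phi_site = r / (1.0 + r) / 2.0
    return ScenarioSpec(
        "sulfite_parallel",
        (
            Transformation(
                "sulfite",
                (
                    Branch("sulfide", phi_hs, epsilon_sulfide, lambda33, param="eps_hs"),
                    Branch("thiosulfate_sulfonate", phi_site, epsilon_sulfonate, lambda33),
                    Branch("thiosulfate_sulfane", phi_site, epsilon_sulfane, lambda33),
                ),
            ),
        ),
        acceptor_species=("sulfite",),
        progress_basis="reactant",
    )


def sulfite_thiosulfate_intermediate(
    epsilon_sulfonate: float = 15.0,
    epsilon_sulfane: float = -15.0,
    epsilon_reduction: float = -7.1,
    thiosulfate_to_sulfide: float = 2.0,
    recycle_sulfonate: bool = False,
    lambda33: float = LAMBDA_REF,
) -> ScenarioSpec:
    """Sulfite → thiosulfate (the sole intermediate) → sulfide.

    All consumed sulfite first enters thiosulfate (sites with the large
    opposed fractionations observed); thiosulfate is then reduced either
    wholesale (default) or site-specifically with the sulfonate recycled to
    the sulfite pool (``recycle_sulfonate=True``, the variant in which the
    residual sulfite is dragged toward the enriched sulfonate composition).
    The relative reduction rate is set so that accumulated thiosulfate S and
    sulfide hold the requested ratio.
    """
    r = thiosulfate_to_sulfide
    make = Transformation(
        "sulfite",
        (
            Branch("thiosulfate_sulfonate", 0.5, epsilon_sulfonate, lambda33),
            Branch("thiosulfate_sulfane", 0.5, epsilon_sulfane, lambda33),
        ),
    )
    if recycle_sulfonate:
        # HS : net-thio = 1 : r with only half of consumed thio-S becoming HS
        c = 2.0 / (2.0 + r)
        consume = (
            Transformation(
                "thiosulfate_sulfane",
                (Branch("sulfide", 1.0, epsilon_reduction, lambda33, param="eps_red"),),
                rate=c / 2.0,
            ),
            Transformation(
                "thiosulfate_sulfonate",
                (Branch("sulfite", 1.0, 0.0, lambda33),),
                rate=c / 2.0,
            ),
        )
    else:
        c = 1.0 / (1.0 + r)
        consume = (
            Transformation(
                "thiosulfate_bulk",
                (Branch("sulfide", 1.0, epsilon_reduction, lambda33, param="eps_red"),),
                rate=c,
            ),
        )
    return ScenarioSpec(
        "sulfite_thiosulfate_intermediate",
        (make,) + consume,
        acceptor_species=("sulfite",),
        progress_basis="reactant",
        notes="recycle_sulfonate=%s" % recycle_sulfonate,
    )


def sulfite_trithionate_stepwise(
    epsilon_sulfonate: float = 15.0,
    epsilon_sulfane: float = -15.0,
    epsilon_s0_step: float = 0.0,
    lambda33: float = LAMBDA_REF,
) -> ScenarioSpec:
    """Stepwise reduction through trithionate (zero residence time).

    Per three sulfite consumed, the two sulfonate moieties cycle back to the
    sulfite pool (enriched, like thiosulfate-sulfonate formation) and the
    central S is reduced to sulfide through an implicit S⁰ intermediate:
    the branch α chains the formation step (``epsilon_sulfane``-like,
    depleted) with the S⁰ → sulfide step ``epsilon_s0_step``, the free
    parameter of the reductio argument.
    """
    return ScenarioSpec(
        "sulfite_trithionate_stepwise",
        (
            Transformation(
                "sulfite",
                (
                    Branch("sulfite", 2.0 / 3.0, epsilon_sulfonate, lambda33),
                    Branch(
                        "sulfide",
                        1.0 / 3.0,
                        epsilon_s0_step,
                        lambda33,
                        epsilon34_offset=epsilon_sulfane,
                        param="eps_s0",
                    ),
                ),
            ),
        ),
        acceptor_species=("sulfite",),
        progress_basis="reactant",
    )


# ---------------------------------------------------------------------------
# scoring against a dataset

def _observed_rows(ds: ExperimentDataset, basis: str):
    """(alignment value, {species: δ³⁴S}) per isotopically characterised point.

    Observed points are aligned with a simulated trajectory through a
    measured observable rather than abstract reaction progress: the
    accumulated sulfide (``basis="product"``) or the remaining acceptor S
    (``basis="reactant"``), both in mM.
    """
    rows = []
    for tp in ds.points:
        if basis == "product":
            p = tp.pool("sulfide")
            align = None if p is None else p.conc
            if align is not None and align <= 0:
                align = None
        else:
            concs = [tp.pool(s) for s in ds.acceptor_species]
            align = (
                None
                if any(p is None for p in concs)
                else sum(p.conc for p in concs)
            )
        obs = {
            p.species: p.comp.delta34
            for p in tp.pools
            if p.comp is not None and p.conc > 0
        }
        son, sane = tp.pool("thiosulfate_sulfonate"), tp.pool("thiosulfate_sulfane")
        if (
            son is not None
            and sane is not None
            and son.comp is not None
            and sane.comp is not None
            and son.conc > 0
        ):
            # sites are equal-mole by construction; equal-weight mix guards
            # against independent measurement noise on the printed concs
            obs["thiosulfate_bulk"] = mix(
                [replace_conc(son, 1.0), replace_conc(sane, 1.0)]
            ).comp.delta34
        if align is not None and tp.t > 0 and obs:
            rows.append((align, obs))
    return rows


def _interp_on_alignment(traj: pd.DataFrame, spec: ScenarioSpec, align, col):
    """Predicted column value where the trajectory matches the alignment."""
    if spec.progress_basis == "product":
        x = traj["sulfide_mM"].to_numpy()
    else:
        x = sum(
            traj[f"{sp}_mM"].to_numpy()
            for sp in spec.acceptor_species
            if f"{sp}_mM" in traj
        )
    y = traj[col].to_numpy()
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size == 0:
        return np.nan
    if x.size > 1 and x[0] > x[-1]:  # reactant axis decreases along progress
        x, y = x[::-1], y[::-1]
    return float(np.interp(align, x, y))


def score_scenarios(
    ds: ExperimentDataset,
    specs: list[ScenarioSpec],
    initial: dict[str, SulfurPool] | None = None,
    step: float = 0.001,
    bounds: tuple[float, float] = (-80.0, 20.0),
    pools: tuple[str, ...] | None = None,
    consumed: float = 0.8,
) -> list[ScenarioPrediction]:
    """Fit each scenario's free fractionations and rank by RMS misfit (‰).

    The misfit is the root-mean-square difference between predicted and
    measured δ³⁴S over every isotopically characterised pool at every time
    point (restricted to ``pools`` when given).  Free parameters (branch
    fractionations flagged in the scenario) are fitted by bounded least
    squares, ε ∈ ``bounds``.  Scenarios are returned sorted by misfit;
    equal-misfit scenarios keep their input order (ties are visible as equal
    ``rms`` values).
    """
    if initial is None:
        initial = {
            p.species: p for p in ds.points[0].pools if p.conc > 0 or p.comp
        }
        for sp in ds.acceptor_species:
            if sp not in initial:
                raise ValueError(f"t=0 lacks the acceptor pool {sp}")

    results = []
    for spec in specs:
        obs = _observed_rows(ds, spec.progress_basis)
        if len(obs) < 1:
            raise ValueError("dataset has no isotopically characterised points")
        names = spec.free_params()
        n_obs = sum(len(o[1]) for o in obs)
        if len(names) > n_obs:
            raise ValueError(
                f"scenario {spec.name}: {len(names)} free parameters but only "
                f"{n_obs} observations"
            )
        def resid(theta, spec=spec, names=names, obs=obs):
            s = spec.with_params(dict(zip(names, theta)))
            pred = simulate_scenario(s, initial, consumed=consumed, step=step)
            out = []
            for align, o in obs:
                for sp_name, d34 in o.items():
                    col = f"{sp_name}_d34"
                    if pools is not None and sp_name not in pools:
                        continue
                    if col not in pred.trajectory:
                        continue
                    v = _interp_on_alignment(pred.trajectory, s, align, col)
                    if np.isfinite(v):
                        out.append(v - d34)
            return np.asarray(out) if out else np.array([np.inf])

        if names:
            x0 = np.clip(
                [
                    next(
                        b.epsilon34
                        for tr in spec.transformations
                        for b in tr.branches
                        if b.param == nm
                    )
                    for nm in names
                ],
                bounds[0],
                bounds[1],
            )
            fit = least_squares(
                resid, x0, bounds=bounds, xtol=1e-10, ftol=1e-10
            )
            theta = fit.x
            res = fit.fun
        else:
            theta = np.array([])
            res = resid(theta)
        fitted = spec.with_params(dict(zip(names, theta)))
        pred = simulate_scenario(fitted, initial, consumed=consumed, step=step)
        pred.params = dict(zip(names, theta))
        pred.rms = float(np.sqrt(np.mean(np.square(res))))
        results.append(pred)
    results.sort(key=lambda p: p.rms)
    return results


def site_specific_offsets(ds: ExperimentDataset) -> pd.DataFrame:
    """δ³⁴S offsets of the thiosulfate sites per time point (‰).

    Columns: sulfonate − bulk, sulfane − bulk, sulfonate − sulfane, where
    bulk is the equal-mole ratio-space mixture of the sites.  The column
    means are attached as ``DataFrame.attrs['mean']``.
    """
    rows = []
    for tp in ds.points:
        son, sane = tp.pool("thiosulfate_sulfonate"), tp.pool("thiosulfate_sulfane")
        if son is None or sane is None or son.comp is None or sane.comp is None:
            continue
        bulk = bulk_from_sites(son, sane) if son.conc > 0 else None
        bulk_d34 = (
            bulk.comp.delta34
            if bulk is not None
            else mix(
                [replace_conc(son, 1.0), replace_conc(sane, 1.0)]
            ).comp.delta34
        )
        rows.append(
            {
                "t": tp.t,
                "sulfonate_minus_bulk": son.comp.delta34 - bulk_d34,
                "sulfane_minus_bulk": sane.comp.delta34 - bulk_d34,
                "sulfonate_minus_sulfane": son.comp.delta34 - sane.comp.delta34,
            }
        )
    if not rows:
        raise ValueError("no time points with both thiosulfate site compositions")
    df = pd.DataFrame(rows)
    df.attrs["mean"] = {
        c: float(df[c].mean()) for c in df.columns if c != "t"
    }
    return df


def replace_conc(pool: SulfurPool, conc: float) -> SulfurPool:
    return SulfurPool(pool.species, conc, pool.sd_conc, pool.comp)
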