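# Methods

This note documents the models, estimators, numerical conventions and
design choices behind `triplesulfur`, and what the synthetic-data tests do
and do not establish about real measurements.

## Isotope algebra and conventions

Compositions are stored as (δ³³S, δ³⁴S) pairs in ‰ against a named
reference frame; Δ³³S is always derived, never stored, using the
mass-dependent reference exponent 0.515 (a named constant).  Two frames
are supported: `experiment-initial` (deltas normalised to the total
sulfur at inoculation, the working frame of the packaged experiment
tables) and `VCDT` (the international scale, used by the high-precision
composition table).  Frame conversion is a multiplication of ratios and
is invertible to < 1e-9 ‰.  The pairwise exponent λ = ln ³³α/ln ³⁴α is
frame-invariant, so λ can be computed on either frame — property-tested.

Mixing is computed on isotopologue mole counts: each mM of sulfur in a
pool contributes ³²S moles `conc/(1 + ³³R + ³⁴R)` and the corresponding
minor-isotope moles.  This conserves every isotope exactly and is the only
correct way to combine Δ³³S values (the Δ³³S of a mixture of two
on-reference-line pools is non-zero).  The absolute reference ratios
(CDT values ³⁴R = 0.0441626, ³³R = 0.0078773) enter only as weights; even
grossly rescaled values move mixed deltas by a few thousandths of a permil
(property-tested).  Pools whose δ³³S was not measured carry NaN in that
channel; they participate in elemental totals and δ³⁴S mixing (their ³²S
weight uses the reference-line δ³³S, a negligible approximation) and
poison only the minor-isotope output.

## Closed-system Rayleigh model and estimators

The reactant relation δ_R(f) = (δ_R,0 + 1000)·f^(α−1) − 1000 is applied
to the quantity x = δ + 1000 with f the mole fraction of reactant
remaining, the standard field convention.  The accumulated product comes
from mass balance of x·moles between the initial inventory and the
residual reactant:

    x_P = [R₀·x_R0·(1 − f^α) + P₀·x_P0] / (R₀·(1 − f) + P₀).

A commonly printed form of this product equation is dimensionally
inconsistent as typeset; the implementation uses the exact mass-balance
form above, with `expm1` guarding the f → 1 limit.  A parallel pool-level
routine (`distill_pools`) evolves both isotopes and does the product
bookkeeping on isotopologue mole counts, so that residual + product
reconstitute the initial inventory at machine precision (ratio-space
conservation, property-tested).  The x-space and mole-count conventions
agree to a few thousandths of a permil at study-scale fractionations;
tests that cross the two conventions use tolerances of that order.

Three per-time-point estimators invert these relations:

* **reactant**: α − 1 = ln(x_R/x_R0)/ln f — uses only the residual
  reactant;
* **product**: solves f^α from the accumulated-product relation — uses
  only the product and the initial reactant composition;
* **paired**: solves (1 − f^α)/((1 − f)·f^(α−1)) = x_P/x_R per point by
  bracketed root finding — uses both measured compositions, and is
  therefore insensitive to a common offset of the pair.

Per-point estimates are averaged with equal weights (the published
convention for these experiments); an inverse-variance weighting option
exists but is off by default.  Points with less than 1% consumption are
excluded by default: a fixed δ-noise maps onto ε with variance ∝ 1/ln²f,
so barely-consumed points are ill-conditioned.  For the thiosulfate
experiment the paired estimator with f = 1 − [sulfide S]/[acceptor S]₀
reproduces the published wholesale-reduction fit and its published
spread; applied to the sulfane site alone it reproduces the published
sulfane-scenario value.  The sulfonate-site analogue does **not**
reproduce the corresponding published value (−8.06 ± 0.80; we obtain
−9.07 ± 0.54 with this estimator and no variant tried reproduces it);
the package computes and reports it without asserting the published
number.  This is documented as an open discrepancy rather than silently
recalibrated.

λ is estimated pairwise (`lambda_between`) between reactant and product
compositions.  Its uncertainty is propagated by seeded Monte Carlo over
Gaussian perturbations of the (δ³⁴S, Δ³³S) inputs (default 10⁴ draws;
stable to a few % against 10⁵ draws and in agreement with first-order
delta-method propagation).  sd(λ) grows steeply as the δ³⁴S separation
shrinks — asserted as strict monotonicity over a separation grid.

## Consumed fraction and cell-specific rates

The reaction coordinate f is product-based by default:
f_consumed = [sulfide S]_t/[acceptor S]₀, which reproduces the printed
consumed-fraction columns of the packaged tables; a reactant-based
alternative is available.  Cell-specific rates are |Δc|/Δt divided by a
cell-density statistic, reported in fmol S cell⁻¹ day⁻¹.  The printed
per-interval rate columns of the packaged tables are reproduced (to
within rounding of the printed concentrations) by the `half_delta`
statistic — half the change in cell count over the interval — which was
calibrated once against those columns and frozen as the default.  The
arithmetic-mean, start-of-interval and logarithmic-mean statistics are
available; the log-mean is exact for exponential growth and is what a
constant true per-cell rate is recovered with in simulation.  Note the
published convention (`half_delta`) reports roughly 2–4× the
integral-consistent per-cell rate for exponentially growing cultures.

## Thiosulfate units

The packaged thiosulfate-bearing tables print thiosulfate concentrations
whose unit (mM molecules vs. mM total S) is internally ambiguous: the
printed consumed-fraction columns require the per-molecule reading
(initial acceptor S = 2 × printed), while a table footnote states total
sulfur.  The default loader uses the per-molecule reading, which
reproduces the printed f columns and the published fits; the
total-sulfur alternative is available via
`load_fixture(..., thiosulfate_units="total_sulfur")` and is flagged in
the dataset notes.  Neither reading is asserted correct.  Thiosulfate is
always represented as its two equal-mole sites, never as a single pool.

## Pathway scenarios

A scenario is a set of transformations (source pool → product branches
with S-mole fractions and per-branch α), executed as forward-Euler
distillation on a reaction-progress grid (default step 0.001 of the
initial acceptor S; halving the step changes trajectories by < 0.01 ‰).
Isotopes are moved as isotopologue parcels with instantaneous-product
ratios α·R_source, so trajectories conserve mass and isotopes exactly;
recycling branches update the receiving pool by exact mixing.  Electron
bookkeeping is validated against nominal site valences (sulfate +6,
sulfite +4, sulfonate +5, sulfane −1, S⁰ 0, sulfide −2): e.g. wholesale
thiosulfate reduction is 8 e⁻ per molecule, sulfonate-only 6, sulfane-only 2.

Scoring aligns observed time points with a trajectory through a measured
observable (accumulated sulfide for thiosulfate scenarios, remaining
acceptor S for sulfite scenarios) rather than abstract progress, fits the
free branch fractionations by bounded least squares (ε ∈ [−80, +20] ‰),
and ranks scenarios by RMS δ³⁴S misfit over all isotopically
characterised pools; ties are visible as equal RMS.  Choices of note:

* the sulfite-experiment branching ratio thiosulfate-S : sulfide-S
  defaults to 2:1 (the observed stoichiometry) and is configurable;
* trithionate is an implicit intermediate with zero residence time: the
  stepwise scenario routes two of three sulfite through an enriched
  sulfonate-like recycle and the third to sulfide through a chained
  (formation × S⁰-reduction) α, whose free second factor is the parameter
  of the published reductio argument — fitting it to the sulfite data
  yields a substantial *inverse* (positive) fractionation, and the direct
  pairwise version of the argument (measured sulfide vs. measured sulfane
  site) exceeds +10 ‰ at both high-precision time points;
* abiotic sulfide+sulfite recombination is not modelled (no rate is
  available to parameterise it).

## Equilibrium β-factors

β-factors follow the Bigeleisen–Mayer product over modes,
(u_h/u_l)·e^{(u_l−u_h)/2}·(1−e^{−u_l})/(1−e^{−u_h}), u = hcν̃/k_BT, with
physical constants from scipy's CODATA table.  Only harmonic frequencies
are used; a uniform scaling factor (0.8928, the HF/6-31G* least-squares
value) is available for sets derived from electronic-structure methods.
The implementation is verified against a 50-digit arbitrary-precision
evaluation for H₂S at 298.15 K, against the classical limit
(β → 1 as 1/T²), and for ln α additivity across species.

The packaged frequency sets are **synthetic**: generated by a classical
point-mass normal-mode model (`triplesulfur.modes`) — literature
equilibrium geometries, a diagonal valence force field calibrated once to
spectroscopic fundamentals of each species, Cartesian Hessian by central
differences, mass-weighted diagonalisation, ³⁴S substitution at the
requested site.  They give physically reasonable magnitudes (sulfate–
sulfide ≈ 77 ‰ at 25 °C, near low-temperature theoretical estimates;
sulfonate–sulfite ≈ +17 ‰, consistent with the observed site enrichment)
and correct temperature dependence, but are not any published curve; no
numerical equilibrium value from the literature is asserted beyond a
loose [50, 90] ‰ window for sulfate–sulfide at 25 °C.  The diagonal force
field cannot separate all bend/stretch fundamentals exactly (rms
deviations of tens of cm⁻¹ for the oxyanions); this limits the sets to
order-of-magnitude fidelity, which is all they are used for.

## Synthetic experiments

The generator emulates the batch design: exponential growth from a small
inoculum, cumulative reduction from integrating a constant per-cell rate
(fmol S cell⁻¹ day⁻¹ × cells mL⁻¹ integrates to mM via 1e-9), isotope
evolution by the closed-system relations (or a full scenario trajectory
for branched chemistry), and Gaussian noise applied to observations only,
with the noiseless truth returned alongside.  One seeded generator drives
all randomness; identical seeds give bit-identical datasets.  Defaults
follow the sulfate-experiment conditions (20 mM acceptor S, 3.4×10⁶
cells/mL, 0.12 h⁻¹, 30 fmol S cell⁻¹ day⁻¹ — the integral-consistent
rate, reaching ~20% consumption by 40 h; noise 0.2 mM, 0.2 ‰ in δ³⁴S,
0.01 ‰ in Δ³³S, 10% relative on cells, the magnitudes of the printed σ
columns).  Thiosulfate-experiment tests use the corresponding conditions
from that table (36 mM S, 1.54×10⁶ cells/mL, 0.13 h⁻¹,
110 fmol S cell⁻¹ day⁻¹, sampling at 0/13/19/33/40 h).  The two
thiosulfate site pools share one concentration-noise draw (one ion-
chromatography measurement underlies both).

Not simulated: lag/stationary-phase physiology, pH-dependent speciation,
abiotic sulfide oxidation, inoculum sulfur blanks.  Passing
parameter-recovery tests therefore shows the estimators are unbiased and
correctly calibrated under the stated noise model — not that real
cultures satisfy that model.

## Test problem sizes

Simulation-based tests use 10–200 replicates of 5–6-time-point
experiments and 50 replicates for scenario self-identification; Monte-
Carlo uncertainty tests use 10⁴–10⁵ draws.  These sizes give stable
statistics (standard errors several times smaller than the asserted
tolerances) while keeping the full suite under a minute.

## Known limitations

* The printed per-point ε values of the sulfate experiments cannot be
  re-derived from raw compositions (none are printed); they are treated
  as data and reproduced through a reconstruct-and-refit cycle.
* The published sulfonate-scenario fractionation is not reproduced by any
  estimator variant implemented (see above).
* The running text and the table block labels of the sulfate experiments
  disagree about which electron donor carries which mean ε (the printed
  per-point values in the lactate-labelled block average to the value the
  text assigns to formate, and vice versa); the fixtures keep the table
  labels and record the discrepancy in their header notes.  The same swap
  affects the quoted peak cell-specific rates.
* Open-system (chemostat) fractionation models, δ³⁶S, enzyme-level
  kinetics and PCM-solvated quantum-chemical frequencies are out of scope.
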