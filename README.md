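# triplesulfur

Multiple sulfur isotope analysis of closed-system (batch) microbial
reduction experiments: triple-isotope algebra, Rayleigh fractionation
fitting, multi-pool mass balance with site-resolved thiosulfate, forward
models of candidate reduction pathways, and equilibrium fractionation
curves from vibrational partition functions.

## Who this is for

Isotope biogeochemists running (or re-analysing) batch cultures of sulfate
reducers grown on sulfate, sulfite or thiosulfate, who need to turn time
series of concentrations and isotope compositions (δ³⁴S, Δ³³S per pool)
into fractionation factors (³⁴ε, ³³λ), check that the measured pools close
elemental and isotopic mass balance, and discriminate between candidate
reduction pathways.

## The model in brief

All deltas are per-mil deviations of isotope ratios from a reference
frame, with the minor-isotope anomaly defined against the mass-dependent
reference line

    Δ³³S = δ³³S − 1000·((1 + δ³⁴S/1000)^0.515 − 1),

and the triple-isotope exponent between two pools ³³λ = ln ³³α / ln ³⁴α,
where ³⁴α = (δ³⁴S_A/1000 + 1)/(δ³⁴S_B/1000 + 1) and ³⁴ε = (³⁴α − 1)·1000.

In a closed system with fraction *f* of reactant remaining, the residual
reactant follows the Rayleigh relation

    δ_R(f) = (δ_R,0 + 1000)·f^(α−1) − 1000,

and the accumulated product follows from isotope mass balance between the
initial inventory and the residual reactant.  Three per-time-point
estimators invert these relations (reactant-only, product-only, and a
paired estimator using both measured compositions at known *f*); per-point
values are averaged with equal weights.  Mixing of pools is always done on
isotope ratios (isotopologue mole counts) — mixing is non-linear in Δ³³S.

Pathway scenarios (e.g. wholesale vs. site-specific thiosulfate reduction,
sulfite reduction through a thiosulfate intermediate with or without
sulfonate recycling) are explicit forward distillations on a reaction
progress grid that conserve every isotopologue exactly; their free
fractionations are fitted to a dataset by bounded least squares and ranked
by RMS misfit.

Equilibrium fractionations come from Bigeleisen–Mayer reduced partition
function ratios (β-factors) over harmonic vibrational frequencies;
1000·(ln β_A − ln β_B) gives the equilibrium ³⁴ε between species A and B
at each temperature.

## Worked example

```python
import triplesulfur as ts

tables = ts.make_fixture_tables()          # packaged batch-experiment tables

ff = ts.epsilon_from_printed(tables["sulfate_lactate"])
print(f"sulfate experiment: 34eps = {ff.epsilon34:.2f} +/- {ff.sd_epsilon34:.2f}")

ff = ts.epsilon_thiosulfate(tables["thiosulfate_lactate"], "bulk")
print(f"wholesale thiosulfate reduction: 34eps = {ff.epsilon34:.2f} +/- {ff.sd_epsilon34:.2f}")

t4 = tables["table4"]
lam = ts.lambda_thiosulfate_bulk(t4, "thiosulfate_lactate", 40.0)
print(f"thiosulfate 40 h: lambda = {lam:.4f}")
```

prints

```
sulfate experiment: 34eps = -4.25 +/- 0.44
wholesale thiosulfate reduction: 34eps = -7.12 +/- 0.18
thiosulfate 40 h: lambda = 0.5119
```

The first line is the mean (±1σ across time points) closed-system
fractionation between sulfate and sulfide for one sulfate-grown culture;
the second is the fractionation of non-site-specific thiosulfate reduction
from the paired reactant/product estimator; the third is the
triple-isotope exponent between bulk thiosulfate (equal-mole ratio-space
mix of its two sites) and product sulfide — below the 0.515 reference
exponent, as kinetic microbial reduction should be.

More narrative walkthroughs live in `examples/` (Rayleigh fits, λ values,
mass-balance closure, pathway ranking, site-specific effects, equilibrium
curves, simulation/recovery).  A thin CLI mirrors the main recipes:

```bash
triplesulfur fit-rayleigh --role paired path/to/dataset.csv
triplesulfur equilibrium-curve --a sulfate --b sulfide --tmin 0 --tmax 100
triplesulfur simulate --seed 1 --out sim.csv
```

## Data formats

Datasets are plain CSV, one row per (time point × pool), with fixed columns
(`experiment_id, t_h, cells_per_ml, cells_rsd_pct, species, conc_mM_S,
sd_conc_mM, d34S_permil, D33S_permil, frame, flags`) and `# key: value`
header lines for the experiment design.  Thiosulfate is always carried as
its two sites (sulfonate and sulfane) in equal moles.  Vibrational
frequency sets are small text files (`name:`/`symmetry_ratio:`/`scale:`
headers, then one `nu_light nu_heavy` pair per mode, cm⁻¹); the packaged
sets are synthetic, generated by the classical harmonic model in
`triplesulfur.modes`.

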