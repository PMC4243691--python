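"""Fit closed-system Rayleigh fractionation factors to the packaged tables.

The two sulfate experiments carry printed per-time-point epsilon values;
their equal-weight means are the experiment-level fractionations.  The
thiosulfate experiment carries residual-reactant and product compositions,
so the paired estimator solves alpha per time point from both.
"""

import triplesulfur as ts

tables = ts.make_fixture_tables()

for name in ("sulfate_lactate", "sulfate_formate"):
    ff = ts.epsilon_from_printed(tables[name])
    print(f"{name:22s} 34eps = {ff.epsilon34:6.2f} +/- {ff.sd_epsilon34:.2f} permil")

for reactant in ("bulk", "sulfonate", "sulfane"):
    ff = ts.epsilon_thiosulfate(tables["thiosulfate_lactate"], reactant)
    print(f"thiosulfate ({reactant:9s}) 34eps = {ff.epsilon34:6.2f} +/- {ff.sd_epsilon34:.2f} permil")

print()
print("A 34eps of -4 to -7 permil means the product sulfide is a few permil")
print("lighter than its precursor; the bulk-thiosulfate value is the")
print("wholesale (non-site-specific) reduction fractionation.")
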