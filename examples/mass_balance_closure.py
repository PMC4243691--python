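"""Check elemental and isotopic mass-balance closure of a batch experiment.

In a closed tube the total sulfur (and its isotope inventory) must stay
constant; residuals against the t = 0 inventory expose measurement error
or unmeasured pools.
"""

import triplesulfur as ts

ds = ts.make_fixture_tables()["thiosulfate_lactate"]
res = ts.residuals(ds)
print(res[["t", "dmass_mM", "dmass_pct", "dd34S_permil"]].to_string(index=False))
print()
print("Mass residuals stay within ~9% of the 36 mM initial S; delta34")
print("residuals (ratio-space mix of all measured pools minus the t=0")
print("total) shrink from ~1.5 permil early to a few tenths late, as the")
print("growing, well-characterised sulfide pool dominates the budget.")
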