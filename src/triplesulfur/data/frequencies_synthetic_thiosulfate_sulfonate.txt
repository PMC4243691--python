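# synthetic frequency set: classical harmonic point-mass model
# (triplesulfur.modes), NOT electronic-structure output
name: thiosulfate_sulfonate
symmetry_ratio: 1
scale: 1
288.6405 287.4909
288.6405 287.4909
419.2756 419.0570
546.5758 545.4079
546.5759 545.4079
660.8346 656.5351
927.3217 914.0729
1038.3416 1023.3159
1038.3416 1023.3160
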