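# synthetic frequency set: classical harmonic point-mass model
# (triplesulfur.modes), NOT electronic-structure output
name: thiosulfate_sulfane
symmetry_ratio: 1
scale: 1
288.6405 286.8603
288.6405 286.8603
419.2756 413.5240
546.5758 546.5756
546.5759 546.5757
660.8346 656.8788
927.3217 925.8184
1038.3416 1038.3332
1038.3416 1038.3332
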