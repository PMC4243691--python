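# synthetic frequency set: classical harmonic point-mass model
# (triplesulfur.modes), NOT electronic-structure output
name: sulfide
symmetry_ratio: 1
scale: 1
1182.9920 1181.9686
2619.3439 2617.0403
2621.9649 2619.5264
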