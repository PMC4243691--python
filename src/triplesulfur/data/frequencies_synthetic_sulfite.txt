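# synthetic frequency set: classical harmonic point-mass model
# (triplesulfur.modes), NOT electronic-structure output
name: sulfite
symmetry_ratio: 1
scale: 1
496.4134 492.0075
532.8138 531.7410
532.8138 531.7411
859.0142 851.2890
981.7605 968.5849
981.7605 968.5849
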