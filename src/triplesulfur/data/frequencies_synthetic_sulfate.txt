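# synthetic frequency set: classical harmonic point-mass model
# (triplesulfur.modes), NOT electronic-structure output
name: sulfate
symmetry_ratio: 1
scale: 1
524.5609 524.5609
524.5609 524.5609
545.3940 542.7933
545.3940 542.7933
545.3940 542.7933
843.3710 843.3710
1147.3603 1130.0488
1147.3603 1130.0488
1147.3603 1130.0488
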