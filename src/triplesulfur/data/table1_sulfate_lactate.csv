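# acceptor: sulfate
# donor: lactate
# initial_acceptor_S_mM: 20.24
# source_table: 1
# label_note: block label as printed; the running text pairs the -5.93 mean with lactate, the printed per-point values in this block average -4.25
experiment_id,t_h,cells_per_ml,cells_rsd_pct,species,conc_mM_S,sd_conc_mM,d34S_permil,D33S_permil,frame,flags
sulfate_lactate,0,3.4e6,5.8,sulfate,20.24,2.33,,,,cssrr=0.0;f_pct=0.0
sulfate_lactate,0,3.4e6,5.8,sulfide,0.01,0.00,,,,
sulfate_lactate,24,12.2e6,25.6,sulfate,20.19,1.03,,,,cssrr=12.8;f_pct=2.2;eps34=-4.02
sulfate_lactate,24,12.2e6,25.6,sulfide,0.45,0.15,,,,
sulfate_lactate,29.4,71.6e6,35.2,sulfate,19.24,0.21,,,,cssrr=142.3;f_pct=6.9;eps34=-4.25
sulfate_lactate,29.4,71.6e6,35.2,sulfide,1.39,0.43,,,,
sulfate_lactate,34.1,309.1e6,10.1,sulfate,17.36,0.15,,,,cssrr=80.7;f_pct=16.2;eps34=-3.87
sulfate_lactate,34.1,309.1e6,10.1,sulfide,3.28,0.29,,,,
sulfate_lactate,39.5,423.9e6,1.3,sulfate,16.56,0.15,,,,cssrr=61.8;f_pct=18.9;eps34=-4.86
sulfate_lactate,39.5,423.9e6,1.3,sulfide,3.82,0.12,,,,
sulfate_lactate,,6.0e6,,sulfate,20.06,0.00,,,,control=nc
sulfate_lactate,,6.2e6,,sulfate,24.51,0.01,,,,control=kc
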