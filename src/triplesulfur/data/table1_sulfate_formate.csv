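# acceptor: sulfate
# donor: formate
# initial_acceptor_S_mM: 18.00
# source_table: 1
# label_note: block label as printed; the running text pairs the -4.25 mean with formate, the printed per-point values in this block average -5.92
experiment_id,t_h,cells_per_ml,cells_rsd_pct,species,conc_mM_S,sd_conc_mM,d34S_permil,D33S_permil,frame,flags
sulfate_formate,0,3.07e6,5.89,sulfate,18.00,0.00,,,,cssrr=0.00;f_pct=0.00
sulfate_formate,0,3.07e6,5.89,sulfide,0.00,,,,,
sulfate_formate,69,6.52e6,12.76,sulfate,15.55,0.94,,,,cssrr=494.48;f_pct=10.28;eps34=-6.55
sulfate_formate,69,6.52e6,12.76,sulfide,1.85,0.30,,,,
sulfate_formate,81,17.69e6,34.16,sulfate,14.38,1.33,,,,cssrr=420.70;f_pct=21.80;eps34=-5.34
sulfate_formate,81,17.69e6,34.16,sulfide,3.92,0.54,,,,
sulfate_formate,104.5,32.21e6,5.47,sulfate,13.42,0.08,,,,cssrr=134.19;f_pct=28.08;eps34=-5.88
sulfate_formate,104.5,32.21e6,5.47,sulfide,5.05,0.15,,,,
sulfate_formate,,,,sulfate,19.06,0.01,,,,control=nc;unparsed_cell_entry=64.18
sulfate_formate,,6.20e6,,sulfate,18.20,0.02,,,,control=kc
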