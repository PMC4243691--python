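# acceptor: sulfite
# donor: lactate
# initial_acceptor_S_mM: 17.11
# source_table: 3
# thiosulfate_units: per_molecule
# units_note: printed [S2O3] read as mM molecules (confirmed by the printed f_S2O3 column, e.g. 2*3.18/17.11 = 37.2%)
# site_note: thiosulfate site delta34 printed as 0.00 at 0 and 20 h transcribed as unmeasured; site compositions are characterised only at 23.4, 26.5 and 30.6 h
experiment_id,t_h,cells_per_ml,cells_rsd_pct,species,conc_mM_S,sd_conc_mM,d34S_permil,D33S_permil,frame,flags
sulfite_lactate,0,2.53e6,26.36,sulfite,17.11,0.50,0.00,,experiment-initial,cssrr=0.00;f_h2s_pct=0.00;f_s2o3_pct=0.00
sulfite_lactate,0,2.53e6,26.36,sulfide,0.06,0.02,,,,
sulfite_lactate,0,2.53e6,26.36,thiosulfate_sulfonate,0.04,0.00,,,,
sulfite_lactate,0,2.53e6,26.36,thiosulfate_sulfane,0.04,0.00,,,,
sulfite_lactate,20,36.55e6,9.59,sulfite,15.10,0.15,0.13,,experiment-initial,cssrr=141.65;f_h2s_pct=1.99;f_s2o3_pct=8.56
sulfite_lactate,20,36.55e6,9.59,sulfide,0.34,0.02,-10.27,,experiment-initial,
sulfite_lactate,20,36.55e6,9.59,thiosulfate_sulfonate,0.73,0.09,,,,printed_zero=1
sulfite_lactate,20,36.55e6,9.59,thiosulfate_sulfane,0.73,0.09,,,,printed_zero=1
sulfite_lactate,23.4,108.29e6,5.14,sulfite,12.80,0.08,0.41,,experiment-initial,cssrr=452.96;f_h2s_pct=4.91;f_s2o3_pct=21.47
sulfite_lactate,23.4,108.29e6,5.14,sulfide,0.84,0.07,-6.14,,experiment-initial,
sulfite_lactate,23.4,108.29e6,5.14,thiosulfate_sulfonate,1.84,0.14,16.78,,experiment-initial,
sulfite_lactate,23.4,108.29e6,5.14,thiosulfate_sulfane,1.84,0.14,-15.19,,experiment-initial,
sulfite_lactate,26.5,227.33e6,3.58,sulfite,9.66,0.16,1.29,,experiment-initial,cssrr=408.33;f_h2s_pct=9.70;f_s2o3_pct=37.20
sulfite_lactate,26.5,227.33e6,3.58,sulfide,1.66,0.06,-3.16,,experiment-initial,
sulfite_lactate,26.5,227.33e6,3.58,thiosulfate_sulfonate,3.18,0.12,15.38,,experiment-initial,
sulfite_lactate,26.5,227.33e6,3.58,thiosulfate_sulfane,3.18,0.12,-13.62,,experiment-initial,
sulfite_lactate,30.6,469.77e6,0.30,sulfite,5.92,0.60,0.61,,experiment-initial,cssrr=180.89;f_h2s_pct=15.55;f_s2o3_pct=52.12
sulfite_lactate,30.6,469.77e6,0.30,sulfide,2.66,0.20,-2.54,,experiment-initial,
sulfite_lactate,30.6,469.77e6,0.30,thiosulfate_sulfonate,4.46,0.82,14.16,,experiment-initial,
sulfite_lactate,30.6,469.77e6,0.30,thiosulfate_sulfane,4.46,0.82,-13.29,,experiment-initial,
sulfite_lactate,,1.56e6,,sulfite,18.23,0.02,,,,control=nc
sulfite_lactate,,1.56e6,,thiosulfate_sulfonate,0.04,,,,,control=nc
sulfite_lactate,,1.56e6,,thiosulfate_sulfane,0.04,,,,,control=nc
sulfite_lactate,,0.20e6,,sulfite,16.72,0.02,,,,control=kc
sulfite_lactate,,0.20e6,,thiosulfate_sulfonate,0.04,,,,,control=kc
sulfite_lactate,,0.20e6,,thiosulfate_sulfane,0.04,,,,,control=kc
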