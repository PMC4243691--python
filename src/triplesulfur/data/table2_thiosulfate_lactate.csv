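# acceptor: thiosulfate
# donor: lactate
# initial_acceptor_S_mM: 36.00
# source_table: 2
# thiosulfate_units: per_molecule
# units_note: printed [S2O3] read as mM molecules (each site pool carries that value as mM S), which reproduces the printed f column (5.26/36.0 = 14.6%); the table footnote's total-sulfur reading is available via the loader
experiment_id,t_h,cells_per_ml,cells_rsd_pct,species,conc_mM_S,sd_conc_mM,d34S_permil,D33S_permil,frame,flags
thiosulfate_lactate,0,1.54e6,0.56,thiosulfate_sulfonate,18.00,0.07,2.16,,experiment-initial,cssrr=0.00;f_pct=0.00
thiosulfate_lactate,0,1.54e6,0.56,thiosulfate_sulfane,18.00,0.07,-2.16,,experiment-initial,
thiosulfate_lactate,0,1.54e6,0.56,sulfide,0.00,0.00,,,,
thiosulfate_lactate,13,21.46e6,0.47,thiosulfate_sulfonate,17.96,0.29,0.03,,experiment-initial,cssrr=134.91;f_pct=2.02
thiosulfate_lactate,13,21.46e6,0.47,thiosulfate_sulfane,17.96,0.29,-2.81,,experiment-initial,
thiosulfate_lactate,13,21.46e6,0.47,sulfide,0.73,0.07,-8.61,,experiment-initial,
thiosulfate_lactate,19,71.45e6,0.27,thiosulfate_sulfonate,16.87,0.28,0.64,,experiment-initial,cssrr=264.91;f_pct=6.62
thiosulfate_lactate,19,71.45e6,0.27,thiosulfate_sulfane,16.87,0.28,-2.61,,experiment-initial,
thiosulfate_lactate,19,71.45e6,0.27,sulfide,2.38,0.15,-8.32,,experiment-initial,
thiosulfate_lactate,33,138.99e6,0.20,thiosulfate_sulfonate,16.11,0.04,3.42,,experiment-initial,cssrr=67.25;f_pct=10.30
thiosulfate_lactate,33,138.99e6,0.20,thiosulfate_sulfane,16.11,0.04,-1.26,,experiment-initial,
thiosulfate_lactate,33,138.99e6,0.20,sulfide,3.71,0.12,-6.67,,experiment-initial,
thiosulfate_lactate,40,300.46e6,0.17,thiosulfate_sulfonate,13.80,0.00,4.34,,experiment-initial,cssrr=66.09;f_pct=14.62
thiosulfate_lactate,40,300.46e6,0.17,thiosulfate_sulfane,13.80,0.00,-1.46,,experiment-initial,
thiosulfate_lactate,40,300.46e6,0.17,sulfide,5.26,0.21,-6.02,,experiment-initial,
thiosulfate_lactate,,0.06e6,0.00,thiosulfate_sulfonate,17.53,,,,,control=nc
thiosulfate_lactate,,0.06e6,0.00,thiosulfate_sulfane,17.53,,,,,control=nc
thiosulfate_lactate,,3.20e6,0.02,thiosulfate_sulfonate,17.76,,,,,control=kc
thiosulfate_lactate,,3.20e6,0.02,thiosulfate_sulfane,17.76,,,,,control=kc
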