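# source_table: 4
# note: high-precision dual-inlet compositions, delta34 and capital-delta33 relative to VCDT
# t_note: sulfate-experiment rows carry no printed sampling time; assigned to the final time point (flag t_assumed)
experiment_id,t_h,cells_per_ml,cells_rsd_pct,species,conc_mM_S,sd_conc_mM,d34S_permil,D33S_permil,frame,flags
sulfate_lactate,39.5,,,sulfate,,,0.27,-0.02,VCDT,t_assumed=1
sulfate_lactate,39.5,,,sulfide,,,-3.95,0.008,VCDT,t_assumed=1
sulfate_formate,104.5,,,sulfate,,,1.76,-0.01,VCDT,t_assumed=1
sulfate_formate,104.5,,,sulfide,,,-5.15,0.016,VCDT,t_assumed=1
sulfite_lactate,26.5,,,sulfite,,,1.29,0.033,VCDT,
sulfite_lactate,26.5,,,sulfide,,,-3.16,0.012,VCDT,
sulfite_lactate,26.5,,,thiosulfate_sulfonate,,,15.38,0.023,VCDT,
sulfite_lactate,26.5,,,thiosulfate_sulfane,,,-13.62,0.002,VCDT,
sulfite_lactate,30.6,,,sulfite,,,0.61,0.038,VCDT,
sulfite_lactate,30.6,,,sulfide,,,-2.54,0.022,VCDT,
sulfite_lactate,30.6,,,thiosulfate_sulfonate,,,14.16,0.041,VCDT,
sulfite_lactate,30.6,,,thiosulfate_sulfane,,,-13.29,0.041,VCDT,
thiosulfate_lactate,0,,,thiosulfate_sulfonate,,,2.16,-0.037,VCDT,
thiosulfate_lactate,0,,,thiosulfate_sulfane,,,-2.16,0.039,VCDT,
thiosulfate_lactate,33,,,sulfide,,,-6.67,0.013,VCDT,
thiosulfate_lactate,33,,,thiosulfate_sulfonate,,,3.42,-0.017,VCDT,
thiosulfate_lactate,33,,,thiosulfate_sulfane,,,-1.26,0.006,VCDT,
thiosulfate_lactate,33,,,elemental_S,,,-5.58,0.019,VCDT,
thiosulfate_lactate,40,,,sulfide,,,-6.02,0.024,VCDT,
thiosulfate_lactate,40,,,thiosulfate_sulfonate,,,4.34,-0.005,VCDT,
thiosulfate_lactate,40,,,thiosulfate_sulfane,,,-1.46,0.009,VCDT,
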