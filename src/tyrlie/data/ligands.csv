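ligand_id,name,hydroxyl_count,charge_class,beta_override,Ki_value,Ki_units,Ki_kind
l-DOPA,"(2S)-2-amino-3-(3,4-dihydroxyphenyl)propanoic acid",2,neutral,0.33,,,none
l-Tyr,"(2S)-2-amino-3-(4-hydroxyphenyl)propanoic acid",1,neutral,0.33,0.1,uM,Kd
TRO,"2-hydroxy-2,4,6-cycloheptatrien-1-one",1,neutral,0.37,0.8,uM,Ki
KA,"5-hydroxy-2-(hydroxymethyl)-4H-pyran-4-one",2,neutral,0.33,3.5,uM,Ki
KA1,"2,4-dihydroxybenzaldehyde",2,neutral,0.33,41.55,uM,Ki
KA2,"3,4-dihydroxybenzaldehyde",2,neutral,0.33,52.96,uM,Ki
KA3,"3-hydroxy-1,2-dimethyl-4(1H)-pyridone",1,neutral,0.37,64,uM,Ki
KA4,"5-hydroxy-4-oxo-4H-pyran-2-carboxylic acid",1,neutral,0.33,145,uM,Ki
KA5,"4-methoxybenzaldehyde",0,neutral,0.43,376,uM,Ki
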