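polymer,metabolite_id,molar_mass_g_per_mmol,weight
protein,glu_c,0.14713,1.0
rna,nmp_c,0.33000,1.0
dna,nmp_c,0.33000,1.0
carb,g6p_c,0.16214,1.0
lipid,lip_c,0.25643,1.0
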