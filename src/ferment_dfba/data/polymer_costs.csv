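polymer,mmol_atp_per_g
protein,29.3
rna,1.2
dna,4.2
carb,6.2
lipid,0.0
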