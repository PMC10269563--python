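variable,g_per_mol
glucose,180.16
fructose,180.16
ethanol,46.07
glycerol,92.09
butanediol,90.12
succinate,118.09
acetate,60.05
erythritol,122.12
isobutanol,74.12
isoamyl_alcohol,88.15
phenylethanol,122.16
mevalonate,148.16
ammonium,18.04
aa1,147.13
aa2,131.17
aa3,165.19
arginine,174.20
oxygen,32.00
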