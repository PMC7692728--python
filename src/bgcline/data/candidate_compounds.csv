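name,exact_mass
alkyl-O-dihydrogeranyl-methoxyhydroquinone-1,486.41
alkyl-O-dihydrogeranyl-methoxyhydroquinone-2,500.42
alkyl-O-dihydrogeranyl-methoxyhydroquinone-3,556.49
alkyl-O-dihydrogeranyl-methoxyhydroquinone-4,570.50
diazepinomicin,462.25
pyrrolomycin-1,353.91
pyrrolomycin-2,322.91
pyrrolomycin-3,305.94
cephamycin-1,579.15
cephamycin-2,446.11
cephamycin-3,659.11
enterobactin,669.14
chlorizidine-1,441.94
chlorizidine-2,415.97
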