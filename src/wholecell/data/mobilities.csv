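ion,charge,lambda_s_cm2_per_mol
Na,1,50.1
K,1,73.5
Cs,1,77.3
NMDG,1,24.3
Ca,2,119.0
Mg,2,106.1
Cl,-1,76.3
Asp,-1,22.05
gluconate,-1,24.3
HCO3,-1,44.5
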