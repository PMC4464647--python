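{
  "name": "pipette_ca_0",
  "salts": [
    ["CsAsp", 100],
    ["CsCl", 40],
    ["Na2ATP", 4],
    ["MgCl2", 1],
    ["EGTA", 10],
    ["HEPES", 10]
  ],
  "pH": 7.2,
  "osmolality_mosm_kg": 295,
  "free_ca_um": 0.0
}
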