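{
  "name": "bath_standard",
  "salts": [
    ["NaCl", 150],
    ["CaCl2", 1.5],
    ["MgCl2", 1],
    ["glucose", 10],
    ["HEPES", 10]
  ],
  "pH": 7.4,
  "osmolality_mosm_kg": 315
}
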