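{
  "name": "bath_hypotonic",
  "salts": [
    ["NaCl", 85],
    ["MgCl2", 2],
    ["CaCl2", 1.5],
    ["glucose", 10],
    ["HEPES", 10]
  ],
  "pH": 7.4,
  "osmolality_mosm_kg": 210
}
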