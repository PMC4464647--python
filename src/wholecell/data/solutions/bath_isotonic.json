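{
  "name": "bath_isotonic",
  "salts": [
    ["NaCl", 85],
    ["MgCl2", 2],
    ["CaCl2", 1.5],
    ["glucose", 10],
    ["HEPES", 10],
    ["mannitol", 125]
  ],
  "pH": 7.4,
  "osmolality_mosm_kg": 315
}
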