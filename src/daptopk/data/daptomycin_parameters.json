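{
  "molecular_weight": 1620.7,
  "log_p": 1.2,
  "solubility_mg_ml": 17.89,
  "pka_acid": 2.98,
  "pka_base": 9.59,
  "blood_to_plasma_ratio": 0.2,
  "vss_per_kg": 0.1,
  "binding_protein": "human serum albumin"
}
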