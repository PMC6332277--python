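{
  "analyte": {
    "name": "tadalafil",
    "mol_weight": 389.4,
    "purity": 1.0,
    "quant_labels": ["H-12"],
    "sites": [
      {"label": "H-12", "shift": 5.91, "n_protons": 2, "j_values": [], "t1": 0.986}
    ]
  },
  "standard": {
    "name": "2,4-dinitrotoluene",
    "mol_weight": 182.14,
    "purity": 1.0,
    "quant_labels": ["H-3", "H-5", "H-6"],
    "sites": [
      {"label": "H-3", "shift": 8.72, "n_protons": 1, "j_values": [2.5], "t1": 3.076},
      {"label": "H-5", "shift": 8.45, "n_protons": 1, "j_values": [8.5, 2.5], "t1": 2.834},
      {"label": "H-6", "shift": 7.82, "n_protons": 1, "j_values": [8.5], "t1": 2.765},
      {"label": "CH3", "shift": 2.63, "n_protons": 3, "j_values": [], "t1": null}
    ]
  }
}
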