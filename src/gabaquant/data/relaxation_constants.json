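{
  "comment": "Default T1/T2 relaxation times (ms) and physical constants for absolute quantification at 3 T. Every value can be overridden through the quantify-module config objects.",
  "relaxation_ms": {
    "GABA": {"t1_ms": 1310.0, "t2_ms": 88.0},
    "water_GM": {"t1_ms": 1820.0, "t2_ms": 99.0},
    "water_WM": {"t1_ms": 1084.0, "t2_ms": 69.0},
    "water_CSF": {"t1_ms": 4163.0, "t2_ms": 503.0},
    "tCho": {"t1_ms": 1140.0, "t2_ms": 230.0},
    "tCr": {"t1_ms": 1110.0, "t2_ms": 163.0},
    "tNAA": {"t1_ms": 1340.0, "t2_ms": 260.0}
  },
  "constants": {
    "w_h2o_mol_per_kg": 55.51,
    "c_gm": 0.82,
    "c_wm": 0.70,
    "c_csf": 0.99,
    "mm_cor": 0.5,
    "eff_gaba": 0.5,
    "n_gaba": 2,
    "n_met": {"tCho": 9, "tCr": 3, "tNAA": 3}
  }
}
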