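{
  "vessel": {"c1_kpa": 36.8, "c2_kpa": 0.0, "d1_kpa": 14.4, "d2": 2.0},
  "calcification": {"c1_kpa": 368.0, "c2_kpa": 0.0, "d1_kpa": 144.0, "d2": 2.0},
  "lipid": {"c1_kpa": 2.0, "c2_kpa": 0.0, "d1_kpa": 2.0, "d2": 1.5},
  "loose_matrix": {"c1_kpa": 18.4, "c2_kpa": 0.0, "d1_kpa": 7.2, "d2": 1.5}
}
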