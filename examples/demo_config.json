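{
  "out_dir": "plastocomp_demo_out",
  "seed": 7,
  "simulate": true,
  "ir_min_len": 2000,
  "n_beta_categories": 5,
  "stages": ["structure", "codon", "repeats", "ssrs", "variability"]
}
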