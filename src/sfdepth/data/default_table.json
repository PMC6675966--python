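{
 "schema": "sfdepth.lut.v1",
 "g": 0.8,
 "n": 1.4,
 "lstar_mm": 1.0,
 "n_packets_per_node": 200000,
 "seed": 20260901,
 "grid": {
  "dz": 0.01,
  "z_cap": 40.0
 }
}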