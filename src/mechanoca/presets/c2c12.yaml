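# C2C12-derived osteoblasts: membrane rupture force 672 +/- 100 nN
curve:
  rupture_force_mean: 672.0
  rupture_force_sd: 100.0
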