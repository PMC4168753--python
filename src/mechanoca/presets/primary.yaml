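# Primary mouse osteoblasts: membrane rupture force 516 +/- 200 nN
curve:
  rupture_force_mean: 516.0
  rupture_force_sd: 200.0
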