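# Ca2+-free, EGTA-containing buffer: responses abolished
population:
  conditions:
    calcium_free: {p_local: 0.0, p_global: 0.0, amount_scale: 1.0}
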