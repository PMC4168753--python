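# Gd3+ block of mechanosensitive channels: responses abolished
population:
  conditions:
    gadolinium: {p_local: 0.0, p_global: 0.0, amount_scale: 1.0}
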