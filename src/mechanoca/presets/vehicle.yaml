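# Ethanol vehicle: indistinguishable from control
population:
  conditions:
    vehicle: {p_local: 0.8, p_global: 0.9, amount_scale: 1.0}
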