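# PLC inhibitor Et-18-OCH3: responder fraction unchanged, global amount reduced
population:
  conditions:
    et18: {p_local: 0.8, p_global: 0.9, amount_scale: 0.4}
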