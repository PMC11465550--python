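name: toy_a_plus_b
states: []
parameters:
- a
- b
constants: {}
odes: {}
outputs:
  y: a + b
init: {}
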