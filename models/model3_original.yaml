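name: model3
states:
- X
- I
parameters:
- r_g
- r_d
- a
- b
constants: {}
odes:
  X: X*r_g/(exp(a*(I - b)) + 1)
  I: -I*r_d + X*r_g/(exp(a*(I - b)) + 1)
outputs:
  X: X
init:
  X: 4.45
  I: 0.0
units:
  X: cells x10^6/mL
  I: cells x10^6/mL
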