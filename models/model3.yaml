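name: model3_augmented
states:
- X
- I
- phi
parameters:
- r_g
- r_d
- a
- r_ab
constants: {}
odes:
  X: X*r_g/(phi*r_ab + 1)
  I: -I*r_d + X*r_g/(phi*r_ab + 1)
  phi: a*phi*(-I*r_d + X*r_g/(phi*r_ab + 1))
outputs:
  X: X
init:
  X: 4.45
  I: 0.0
  phi: 1.0
units:
  phi: a.u.
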