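name: model2
states:
- Glucose
- Lactate
- X
parameters:
- r_glu
- r_lac
- mu_max
- km_glu
- ki_lac
constants:
  D_r: 0.033
  GF: 7.0
odes:
  Glucose: D_r*(GF - Glucose) - X*r_glu
  Lactate: -D_r*Lactate + X*r_lac
  X: X*(-D_r + Glucose*ki_lac*mu_max/((Glucose + km_glu)*(Lactate**2 + ki_lac)))
outputs:
  Glucose: Glucose
  Lactate: Lactate
  X: X
init:
  Glucose: 1.01
  Lactate: 3.98
  X: 0.46
units:
  Glucose: mM
  Lactate: mM
  X: cells x10^6/mL
  D_r: hr^-1
  GF: mM
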