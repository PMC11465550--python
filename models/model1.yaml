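name: model1
states:
- mRNA
- Protein
parameters:
- k1
- k2
- k3
- k4
constants: {}
odes:
  mRNA: k1 - k2*mRNA
  Protein: -Protein*k4 + k3*mRNA
outputs:
  mRNA: mRNA
  Protein: Protein
init:
  mRNA: 2.5
  Protein: 6.5
units:
  mRNA: a.u.
  Protein: a.u.
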