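# Hyperbolic discrimination-line coefficients, Qlim = a*sqrt(QAlb^2 + b) - c.
# One block per analyte; all values dimensionless.
IgG:
  a: 0.93
  b: 6.0e-6
  c: 1.7e-3
IgA:
  a: 0.77
  b: 23.0e-6
  c: 3.1e-3
IgM:
  a: 0.67
  b: 120.0e-6
  c: 7.1e-3
FLCkappa:
  a: 3.27
  b: 33.0e-6
  c: 8.2e-3
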