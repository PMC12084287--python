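# Default run configuration: central parameter values on a 20x20 hexagonal
# grid with zero boundary conditions.  Every key may be overridden; the
# parameters block lists the shipped central values explicitly for
# reference (identical to hesnotch.default_parameters()).
framework: ode
lattice:
  rows: 20
  cols: 20
  bc: zero
t_end: 3000.0
output_dt: 1.0
seed: 0
s: 1.0
replicates: 1
parameters:
  alpha_D: 0.018
  alpha_N: 6.0
  alpha_M: 0.017
  alpha_P: 0.14
  alpha_n: 0.0049
  K_M: 0.050
  K_n: 0.030
  k: 1
  h: 4
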