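# Derivative controller SSA-vs-analytics validation circuit:
# h=1, no external disturbance (x = x_bar with probability one),
# k_y=2, gamma_y=0.2, <B_y>=20, <B_z>=1, k_z=gamma_z, shifted-geometric
# bursts.  gamma_z is swept (with k_z = gamma_z) to vary the gain
# f_d = gamma_y/gamma_z; the stored value is one representative point.
circuit:
  topology: derivative
  disturbance:
    mode: none
    level: 1.0
  target:
    burst_rate: 2.0
    decay_rate: 0.2
    burst: {kind: shifted_geometric, mean_size: 20}
  sensor:
    burst_rate: 1.0                    # k_z = gamma_z
    decay_rate: 1.0
    burst: {kind: shifted_geometric, mean_size: 1}
  regulation:
    variant: ratio_derivative
    hill_coeff: 1.0
sweep:
  variable: gamma_z
  grid: [0.4, 0.8, 1.2, 2.0, 3.0, 4.0]
  engines: [lna, ssa]
  normalization: none
  couple_kz_to_gamma_z: true
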