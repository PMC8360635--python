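# Derivative controller, gain sweep of the noise components.
# Caption-level parameters: CV2_int=0.25, CV2_Z=0.1, CV2_X=0.7,
# gamma_z = 3*gamma_y.  The disturbance time-scale prints ambiguously in
# the source ("gamma_x=15gamma_y" with flattened fraction); the default is
# the slow-disturbance reading gamma_x = gamma_y/5, with the fast reading
# preserved in gamma_x_alt.
noise_inputs:
  cv2_int: 0.25
  cv2_x: 0.7
  cv2_z: 0.1
  gamma_y: 1.0
  gamma_z: 3.0
  gamma_x: 0.2
  gamma_x_alt: 15.0
circuit:
  topology: derivative
  disturbance:
    mode: bursty
    params:
      burst_rate: 0.2857142857142857   # x_bar = 10, CV2_X = 0.7
      decay_rate: 0.2
      burst: {kind: shifted_geometric, mean_size: 7}
  target:
    burst_rate: 8.0                    # ybar = 100, CV2_int = 0.25
    decay_rate: 1.0
    burst: {kind: shifted_geometric, mean_size: 25}
  sensor:
    burst_rate: 0.3                    # zbar = 50, CV2_Z = 0.1
    decay_rate: 3.0
    burst: {kind: shifted_geometric, mean_size: 5}
  regulation:
    variant: ratio_derivative
    hill_coeff: 1.0                    # f_d = h*gamma_y/gamma_z = 1/3
sweep:
  variable: gain
  grid: [0.0, 0.05, 0.1, 0.2, 0.33, 0.5, 0.75, 1.0, 1.5, 2.0]
  engines: [formulas]
  normalization: open_loop_total
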