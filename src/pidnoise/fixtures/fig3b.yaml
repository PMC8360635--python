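# Integral controller, gain sweep of the noise components.
# Caption-level parameters: CV2_X=0.5, k_z=gamma_y, zbar/ybar=1;
# gamma_y = 3*gamma_x and CV2_int=0.2 from the companion panel.
noise_inputs:
  cv2_int: 0.2
  cv2_x: 0.5
  cv2_z: 0.1
  gamma_y: 1.0
  gamma_x: 0.3333333333333333
  k_z: 1.0
  ybar: 100.0
  zbar: 100.0
circuit:
  topology: integral
  disturbance:
    mode: bursty
    params:
      burst_rate: 0.6666666666666666   # x_bar = 20, CV2_X = 0.5
      decay_rate: 0.3333333333333333
      burst: {kind: shifted_geometric, mean_size: 10}
  target:
    burst_rate: 10.0                   # open-loop mean 200, set point 100
    decay_rate: 1.0
    burst: {kind: shifted_geometric, mean_size: 20}
  sensor:
    burst_rate: 1.0                    # k_z = gamma_y
    decay_rate: 1.0                    # inert: zero-order decay k_z*y_set
    burst: {kind: shifted_geometric, mean_size: 10}
  regulation:
    variant: zero_order_integral
    half_max: 100.0                    # zbar = 100 at g = 1/2, h = 1
    hill_coeff: 1.0
    set_point: 100.0
sweep:
  variable: gain
  grid: [0.02, 0.05, 0.1, 0.2, 0.35, 0.5, 0.75, 1.0, 1.5, 2.0]
  engines: [formulas]
  normalization: zero_gain_total
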