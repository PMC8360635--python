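# Proportional controller, gain sweep of the three-component noise split.
# The noise_inputs block carries the caption-level parameters
# (CV2_Z=0.4, CV2_int=CV2_X=0.2, gamma_z = 5*gamma_y = 15*gamma_x) and is
# authoritative for the formulas-engine curves; the circuit below is a
# concrete realization whose open-loop operating point matches them.
noise_inputs:
  cv2_int: 0.2
  cv2_x: 0.2
  cv2_z: 0.4
  gamma_y: 1.0
  gamma_z: 5.0
  gamma_x: 0.3333333333333333
circuit:
  topology: proportional
  disturbance:
    mode: bursty
    params:
      burst_rate: 1.6666666666666667   # x_bar = 50
      decay_rate: 0.3333333333333333
      burst: {kind: shifted_geometric, mean_size: 10}
  target:
    burst_rate: 5.0                    # open-loop mean 100
    decay_rate: 1.0
    burst: {kind: shifted_geometric, mean_size: 20}
  sensor:
    burst_rate: 0.125
    decay_rate: 5.0
    burst: {kind: shifted_geometric, mean_size: 4}
  regulation:
    variant: hill_repression
    half_max: 10.0
    hill_coeff: 2.0
sweep:
  variable: gain
  grid: [0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0]
  engines: [formulas]
  normalization: zero_gain_total
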