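# Smooth travelling wave from a Heaviside step: two-rate diffusivity with
# aggregation (D_i > 4 D_g), logistic growth. Measured front speed ~0.862,
# approaching c* = 2 sqrt(lambda D_i) ~ 0.866 under refinement.
experiment: pde-speed
model:
  d_i: 0.25
  d_g: 0.05
  lam: 0.75
x_min: 0.0
x_max: 100.0
dx: 0.1
dt: 0.01
t_final: 60.0
ic: heaviside
step_position: 40.0
front_threshold: 1.0e-5
fit_window: [0.0, 60.0]
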