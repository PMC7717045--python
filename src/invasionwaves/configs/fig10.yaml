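# Shock-fronted wave: PDE simulation with D(u) = (u - 0.1)(u - 0.3) from a
# Heaviside step; the front travels at ~0.3 with a persistent steep
# interior gradient.
experiment: shock-demo
model:
  poly_coeffs: [0.03, -0.4, 1.0]
  lam: 0.75
x_min: 0.0
x_max: 100.0
dx: 0.1
dt: 0.01
t_final: 50.0
ic: heaviside
step_position: 40.0
front_threshold: 1.0e-5
fit_window: [0.0, 50.0]
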