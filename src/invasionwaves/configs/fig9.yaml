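# Desingularised phase portrait for the shifted quadratic diffusivity
# D(u) = (u - 0.1)(u - 0.3) at c = 0.3: (0,0) is a node but (beta,0) = (0.3,0)
# is a spiral, so no smooth wave crosses the upper wall.
experiment: phase-portrait
model:
  poly_coeffs: [0.03, -0.4, 1.0]
  lam: 0.75
c: 0.3
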