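# Phase portrait at a speed between the node/spiral threshold (~0.289) and
# c* (~0.866): the origin is a stable spiral and the lower connecting orbit
# oscillates below u = 0.
experiment: phase-portrait
model:
  d_i: 0.25
  d_g: 0.05
  lam: 0.75
c: 0.4
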