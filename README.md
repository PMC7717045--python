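# invasionwaves

Travelling-wave analysis of a collective cell-invasion model whose
nonlinear diffusivity goes negative.

## The problem

Invading cell populations mix fast *leader* (isolated) cells with slower
*follower* (grouped) cells. A one-dimensional lattice exclusion process
that lets isolated agents (both nearest neighbours vacant) and grouped
agents move, proliferate and die at different rates has the mean-field
continuum limit

    U_t = (D(U) U_x)_x + R(U),
    D(U) = D_i (1 − 4U + 3U²) + D_g (4U − 3U²),      R(U) = λ U (1 − U),

where `U(x, t)` is the agent density, `D_i`, `D_g` are the isolated/grouped
diffusivities and `λ` the proliferation rate. When `D_i > 4 D_g`
(aggregation), `D` is convex and **negative** on an interior interval
`(α, β)` with `1/3 < α < 2/3 < β < 1`: the PDE is locally
backward-parabolic, yet it still propagates smooth invasion fronts.

This package implements the full computational analysis of those fronts:

- **`invasionwaves.model`** — diffusivity/kinetic families, the sign
  regime and roots `α, β`, and the closed-form speed thresholds: the
  minimum wave speed `c* = 2√(λ D_i)`, the node/spiral threshold
  `2√(D'(β) R(β))` at the upper root, and the bracket `S₂ ≤ ĉ ≤ S₁` for
  positive-definite `D`.
- **`invasionwaves.pde`** — explicit conservative finite differences with
  no-flux boundaries, leading-edge tracking `L(t)` and front-speed fits.
- **`invasionwaves.phaseplane`** — the travelling-wave ODE as a singular
  planar system `D(u) u' = p`, `D(u) p' = −c p − D(u) R(u)`, its
  desingularisation by the stretched variable `dz = D(u) dξ`, equilibrium
  classification, invariant-region verification, heteroclinic shooting,
  and assembly of the monotone wave `u(z)` through the two "holes in the
  wall" `(α, 0)`, `(β, 0)` where `D` vanishes.
- **`invasionwaves.spectral`** — essential/absolute spectra of the
  linearisation from the far-field dispersion relations; the rightmost
  absolute-spectrum point `K₊ = λ − c²/(4 D_i)` crosses zero exactly at
  `c*`, so slower waves are absolutely unstable while `c ≥ c*` admits
  stabilising exponential weights, ideally `ν = c/(2 D(0))`.
- **`invasionwaves.lattice`** — the discrete generator itself: the
  deterministic mean-field occupancy recurrence and a stochastic
  agent-based realisation, with the parameter map
  `D = P_m Δ²/(2τ)`, `λ = P_p/τ`, `K = P_d/τ`.
- **`invasionwaves.pipeline` / CLI** — named end-to-end experiments with
  manifests (`simulate-pde`, `wave-construct`, `phase-portrait`,
  `spectrum`, `lattice`, `reproduce fig2|fig5|fig9|fig10`).

## Worked example

```python
from invasionwaves.model import (TwoRateDiffusivity, LogisticKinetic, ModelSpec,
                                 min_wave_speed, beta_node_threshold, diffusivity_roots)
from invasionwaves.phaseplane import construct_wave_orbits, assemble_wave
from invasionwaves.spectral import classify_stability

m = ModelSpec(TwoRateDiffusivity(d_i=0.25, d_g=0.05), LogisticKinetic(lam=0.75))
regime = diffusivity_roots(m.D)
c_star = min_wave_speed(m.D, m.R)
print(regime.alpha, regime.beta)          # 0.4999999999999999 0.8333333333333334
print(c_star)                             # 0.8660254037844386
print(beta_node_threshold(m.D, m.R))      # 0.28867513459481287

wave = assemble_wave(construct_wave_orbits(m, c_star), m, c_star)
print(wave.u.min(), wave.u.max())         # 9.284957080284082e-07 0.9999999000852948

print(classify_stability(m, 0.4).verdict)     # absolutely_unstable
print(classify_stability(m, c_star).verdict)  # weight_stabilisable
```

The diffusivity vanishes at `α = 0.5` and `β = 5/6 ≈ 0.83`; the minimum
wave speed `c* ≈ 0.866` depends only on the *isolated*-agent diffusivity —
invasion speed is set by individual behaviour. Between the node/spiral
threshold `≈ 0.289` and `c*`, the phase-plane construction still succeeds
but the tail spirals below zero density (no biologically admissible wave),
and the spectral verdict explains why such waves are never observed in
simulations: they are absolutely unstable.

A figure-level experiment from the shell:

```sh
invasionwaves reproduce fig2 --out out/fig2
# speed: 0.8620821333215714   (Heaviside start, dx=0.1, dt=0.01, t to 60)
```

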