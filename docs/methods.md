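# Methods

## Model

The continuum model is the nonlinear diffusion–reaction equation
`U_t = (D(U) U_x)_x + R(U)` on the line, with the two-rate diffusivity
`D(U) = D_i(1 − 4U + 3U²) + D_g(4U − 3U²)` and logistic growth
`R(U) = λU(1 − U)`. It is the mean-field limit of a lattice exclusion
process in which agents are classified at event time as isolated (both
nearest neighbours vacant, diffusivity `D_i`) or grouped (`D_g`); the
general kinetics with type-dependent proliferation (`λ_i`, `λ_g`) and
death (`K_i`, `K_g`) are implemented but the reference reduction is
`λ_i = λ_g = λ`, `K_i = K_g = 0`.

Units are model units throughout: densities are site-occupancy fractions
in `[0, 1]`, diffusivities length²/time, rates 1/time. Reference
parameters: `D_i = 0.25`, `D_g = 0.05`, `λ = 0.75`, giving sign-change
roots `α = 1/2`, `β = 5/6`, minimum wave speed `c* = 2√(λD_i) ≈ 0.866`
and node/spiral threshold `2√(D'(β)R(β)) ≈ 0.289`. The shock-fronted
demonstration uses `D(U) = (U − 0.1)(U − 0.3)` for which the two
thresholds swap order (0.3 vs ≈ 0.355), so no smooth wave exists at the
selected speed.

All evaluations accept `u` outside `[0, 1]` without clamping (phase-plane
and PDE solvers overshoot); sign and threshold claims are only asserted on
`[0, 1]`. Root finding uses closed forms up to degree 2 and companion-matrix
roots above, keeping real roots in `[0, 1]`. The degenerate boundary
`D_i = 4D_g` is reported as its own regime (`α = β = 2/3`) rather than
folded into the strict sign-changing case. The supremum defining the
positive-definite speed bound `S₁` is located on a 10⁴-point grid and
polished by bounded scalar minimisation to `1e−10` in `u`; a 10⁶-point
brute-force grid is kept as an independent cross-check in the tests.

## Phase-plane wave construction

With `p := D(u) du/dz` the travelling-wave ODE becomes a planar system
that is singular on the walls `u = α, β`; the stretched variable
`dz = D(u) dξ` removes the walls at the cost of reversing orientation
where `D < 0`. The wave is built from the three heteroclinics of the
desingularised flow, shot from the saddles:

- offset `ε = 1e−7` along the unit-normalised unstable eigenvector, with
  the sign chosen by the requested direction of `u`;
- RK45 with `rtol = 1e−10`, `atol = 1e−12`, dense output resampled on
  4000 uniform ξ-points; termination inside a ball of radius `1e−8`
  around node targets and `1e−6` around spiral targets (node convergence
  is exponential, so this terminates; for spirals the larger ball absorbs
  the winding), or on leaving the strip `u ∈ [−0.1, 1.1]`;
- the wave coordinate is carried as an augmented state `dz/dξ = D(u)`, so
  the removable `0/0` of `dz/du = D(u)/p` at the holes never has to be
  special-cased and `z` inherits the integrator's error control;
- assembly flips the middle orbit's sample order (the backward-diffusion
  interval reverses orientation) rather than re-integrating — the two
  parametrisations trace the same point set — translates segments to join
  at the holes, and anchors `u(0) = 1/2` when `α ≥ 1/2`, else `α/2`
  (translation is arbitrary; the anchor just stays interior to the final
  segment). The hole passage itself is not proven here (that requires a
  singular-perturbation embedding); instead the assembled profile is
  validated a posteriori by the travelling-wave ODE residual, evaluated
  by finite differences on a uniform z-resampling and masked within
  `|u − α|, |u − β| < 0.02` of the holes. At `c = c*` the maximum
  residual is below `1e−7`, well under the `1e−4` acceptance level, and
  the profile is invariant under tolerance halving to better than `1e−5`.

Interior zeros of `p` are rejected on the upper and middle segments
(they would contradict monotonicity); the lower segment is allowed to
oscillate, because for speeds between the node/spiral threshold and `c*`
the origin is a spiral and the tail legitimately dips below zero — that
oscillation is the point of the construction at such speeds.

The vertical-tangent count used by the point-spectrum argument is the
number of interior sign changes of `du` along a sampled curve, with a
relative jitter floor of `1e−9` so that integrator noise near the
equilibria is not counted.

## PDE scheme and front-speed protocol

Forward Euler on the conservative flux form with interface diffusivities
`D_{j+1/2} = (D(u_j) + D(u_{j+1}))/2` and zero boundary fluxes. The
interface average is over *diffusivities*, not densities: evaluating `D`
at the mean interface density would place a sharp 1→0 step exactly on a
zero of `D` whenever `D(1/2) = 0` (true for the reference parameters),
making the step a spurious fixed point of the discretisation. No explicit
regularisation of the backward interval is added; the grid itself
regularises, so `dx` is a physical-fidelity parameter and is recorded in
every manifest. The explicit step obeys the budget
`max_{[0,1]} |D| · dt/dx² ≤ 0.45`; when a requested `dt` violates it the
solver reduces `dt` to one significant digit below the bound and logs the
adjustment (the shifted quadratic peaks at 0.63, so the default 0.01
becomes 0.007).

The leading edge `L(t)` is the left-most grid point with `u` below `1e−5`
(half-open step convention: `u = 1` strictly left of the step; any fixed
convention shifts `L` by at most `dx` and not the fitted slope). The
figure-level speed is the least-squares slope of the **entire** recorded
track from `t = 0`. The reasons are quantitative: a pulled front from
steep data approaches its asymptotic speed from below with an `O(1/t)`
deficit (≈ 0.012 over `t ∈ [30, 60]`), and the asymptotic speed of the
discretised dynamics at `dx = 0.1`, `dt = 0.01` — computed from the
discrete dispersion relation — is `0.861`, below `c* = 0.866`. A
late-window fit therefore reports ≈ 0.851 no matter how accurate the
scheme, while the full-track fit (whose early diffusive transient offsets
the late slow convergence) gives `0.8621` at the reference resolution,
`0.8659` at `dx = 0.05`, `dt = 0.0025` — converging to `c*` under
refinement, which is the behaviour the measurement is meant to expose.
The generic `estimate_speed` keeps a last-50% default window, accepts
explicit windows, reports the residual RMS, and rejects fits in which the
edge came within `5 dx` of the boundary. Standard problem sizes: domain
`[0, 100]`, step at `x = 40`, `t` to 60 (smooth) or 50 (shock), chosen so
the edge stays clear of the right boundary.

## Spectra and weights

The essential and absolute spectra are set by the constant far-field
matrices of the desingularised linearisation, since `D > 0` at both rest
states. All closed forms use the principal square root, and "rightmost
point" statements live on the real axis where these sets are half-lines.
The admissible-weight interval is computed as the root interval of the
quadratic `D(0)ν² − cν + R'(0) < 0` — equivalently
`(c ∓ √(c² − c*²))/(2D(0))` — rather than from any printed endpoint
formula; it is empty for `c < c*` and degenerates to the point
`c*/(2D(0))` at `c = c*` (a `1e−12`-scaled guard absorbs the roundoff of
the double root, and the verdict comparison `K₊ ≤ 0` carries a `1e−14`
guard so the boundary sits at `c*` to machine precision, with the origin
on the stabilisable side). Along the wave, the linearisation coefficient
`B = D'(û) dû/dz` is evaluated through the orbit's `p` as `p/D(û)`, with
the removable limit at the holes taken from the local eigen-data. The
rotation rate of the eigenfunction line through the vertical `q = 0` is
oriented to be `+1` — the sign is a convention for the angle's
orientation; the substance is its unit magnitude and independence of the
spectral parameter, which makes the vertical-tangent count a monotone
eigenvalue counter. Full point-spectrum machinery (root finding in the
spectral parameter) is out of scope; only the tangent-count comparison is
exposed.

## The lattice generator

The generator emulates the discrete study conditions themselves: a 1-D
single-occupancy lattice, agents classified isolated/grouped at action
time, per-step probabilities `(P_m, P_p, P_d)` per class, and the
diffusive mapping `Δ = 0.1`, `τ = 0.01` so that
`P_m^i = 0.5, P_m^g = 0.1, P_p = 0.0075` reproduce the reference
continuum parameters exactly.

*Mean field.* The occupancy balance is implemented in its equivalent
bond-flux form: every motility term is a transfer across one bond (with
the isolated class carrying the second-neighbour vacancy factor) and
every proliferation term a birth across one bond. Interior sites
reproduce the nine-bracket balance term for term — an independent direct
transcription of the brackets is kept in the tests as a
dual-transcription oracle — while the flux form telescopes, so
motility-only dynamics conserve total occupancy to machine precision.
Off-lattice ghosts are vacant and cross-boundary transfers are dropped
(an attempted step off the lattice aborts), the discrete analogue of the
no-flux condition; edge-copied ghost sites were rejected because they
inject mass. Occupancies leaving `[0, 1]` raise, they are never clamped.

*Stochastic.* One step processes the agents present at the start of the
step in uniformly shuffled order; each classifies itself from the current
configuration, then attempts a move to a uniformly chosen neighbour
(aborted if occupied or off-lattice), a daughter deposition under the
same rule, and death. Exclusion guarantees a listed agent is still at its
site when processed, so the schedule is well defined. The kernel is
numba-compiled; all randomness is drawn from a caller-supplied numpy
generator, making runs bit-reproducible for a fixed seed. Calibration:
single-agent mean-square displacement matches `2 D_i t` over 1500–2000
replicates; agent number is conserved exactly without birth/death; a full
lattice admits no births.

*What the generator does and does not show.* The mean-field recurrence at
the mapped parameters reproduces the PDE front speed to better than 1%
(matched domain, duration and fit protocol) — the continuum limit is
implemented correctly. The stochastic front, however, travels markedly
slower (≈ 0.26–0.36 vs ≈ 0.73–0.87 for the half-density edge protocol at
these parameters). This is real physics, not a bug: pulled fronts in
discrete-particle systems are slowed by a cutoff correction of order
`1/ln²N` with `N` the number of particles across the front width, and at
`Δ = 0.1` the front width `1/γ ≈ 0.58` spans only ~6 single-occupancy
sites, so the correction is order one. Closing the gap would require
`N ~ 10⁶` sites per front width, i.e. lattice spacings far beyond any
practical refinement. Tests therefore assert the validated facts — the
calibrations above, exact conservation laws, mean-field/PDE agreement,
and that the averaged stochastic front never outruns its mean-field
limit — and the package makes no claim that 1-D single-occupancy
stochastic fronts attain the continuum speed. Agreement reported in the
agent-based literature typically involves column-averaged 2-D lattices,
whose many agents per column suppress exactly this fluctuation effect;
2-D lattices are out of scope here. Standard stochastic problem sizes:
1000 sites, 3000 steps (`t = 30`), 200 replicates analysed in 20 groups
of 10 for a group-level standard error.

## Experiments and reproducibility

Every named experiment writes a manifest echoing the full configuration
and package version; re-running a configuration produces byte-identical
results. Profile comparisons fit a single translation by coarse scan plus
bounded refinement of the sup-norm on the overlapping window; the
assembled wave at the measured speed matches the late-time simulated
front to better than `2e−2` in sup-norm — a scheme-limited figure (the
grid regularisation smears the front over a few cells), not a statement
about the exact wave.

## Known limitations

- Well-posedness of the backward-parabolic PDE is not addressed; the
  scheme's grid-scale regularisation selects one of possibly several
  regularisation limits, which matters in principle for shock structure.
- No shock construction (equal-area or regularisation-limit rules) for
  the shifted-quadratic case: the simulation exhibits the shock, the
  phase plane explains why no smooth wave exists, nothing more.
- No minimality claim for the speed thresholds of general polynomial
  diffusivities: the closed-form `c*` is the minimum wave speed for the
  two-rate family; for other sign-changing `D` the module exposes the
  thresholds without asserting wave-speed selection.
- Diffusivities with more than two sign changes and type-memory beyond
  nearest-neighbour classification are out of scope.
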