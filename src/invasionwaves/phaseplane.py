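"""Geometric construction of the travelling wave.

The travelling-wave ODE  (D(u) u')' + c u' + R(u) = 0  becomes, with
p := D(u) du/dz, the singular planar system

    D(u) du/dz = p,      D(u) dp/dz = -c p - D(u) R(u),

which is undefined on the walls of singularities u = alpha, u = beta where
D vanishes. The stretched variable xi with D(u) dxi = dz removes the walls:

    du/dxi = p,          dp/dxi = -c p - D(u) R(u).

Where D < 0 the reparametrisation reverses orientation, so a single
heteroclinic orbit of the singular system from (1,0) to (0,0) through the
holes in the wall (alpha,0), (beta,0) splits into three heteroclinics of
the desingularised flow: (1,0)->(beta,0), (alpha,0)->(beta,0) and
(alpha,0)->(0,0). This module classifies the equilibria, verifies the
invariant regions behind the existence proof, shoots the three orbits along
saddle eigenvectors, and reassembles the monotone wave profile u(z).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline

from .model import ModelSpec, diffusivity_roots, flux_derivative_F

__all__ = [
    "PlanarState",
    "EquilibriumInfo",
    "Orbit",
    "TravellingWaveProfile",
    "RegionSpec",
    "IntegratorControls",
    "WallSingularityError",
    "ShootingError",
    "desingularised_rhs",
    "singular_rhs",
    "find_equilibria",
    "check_slope_ordering",
    "verify_invariant_region",
    "shoot_manifold",
    "construct_wave_orbits",
    "assemble_wave",
    "count_vertical_tangents",
]


class WallSingularityError(ZeroDivisionError):
    """Evaluation of the singular system too close to a wall u with D(u)=0."""


class ShootingError(RuntimeError):
    """A shot manifold failed to connect to any equilibrium."""


@dataclass(frozen=True)
class PlanarState:
    u: float
    p: float


@dataclass(frozen=True)
class EquilibriumInfo:
    label: str                 # one of "(0,0)", "(alpha,0)", "(beta,0)", "(1,0)"
    u: float
    eigenvalues: tuple[complex, complex]   # (lambda_+, lambda_-)
    eigenvectors: tuple[tuple[complex, complex], tuple[complex, complex]]
    classification: str        # saddle | stable_node | stable_spiral

    @property
    def location(self) -> PlanarState:
        return PlanarState(self.u, 0.0)


@dataclass
class Orbit:
    """A sampled trajectory of the desingularised flow, with the wave
    coordinate z integrated alongside (dz/dxi = D(u))."""

    xi: np.ndarray
    u: np.ndarray
    p: np.ndarray
    z: np.ndarray
    origin_label: str
    target_label: str | None
    c: float


@dataclass
class TravellingWaveProfile:
    """The assembled monotone wave u(z) with speed c; p = D(u) du/dz is
    kept so that linearised quantities (du/dz = p/D) stay evaluable."""

    z: np.ndarray
    u: np.ndarray
    p: np.ndarray
    c: float

    def interpolant(self) -> CubicSpline:
        return CubicSpline(self.z, self.u)

    def to_csv(self, path, model: ModelSpec | None = None, **meta) -> None:
        import pandas as pd

        pd.DataFrame({"z": self.z, "u": self.u, "p": self.p}).to_csv(path, index=False)
        sidecar = dict(c=self.c, **meta)
        if model is not None:
            from .model import model_to_config

            sidecar["model"] = model_to_config(model)
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)


@dataclass(frozen=True)
class RegionSpec:
    """Invariant triangle of the existence proof: R1 below p=0 on (0,alpha)
    bounded by the line p = mu*u; R2/R3 on (alpha,1) bounded by
    p = mu*(u-beta)."""

    name: str       # R1 | R2 | R3
    mu: float
    anchor: float   # u-root of the straight-line boundary (0 for l1, beta for l2)

    def __post_init__(self) -> None:
        if self.mu >= 0:
            raise ValueError("boundary slope must be negative")


@dataclass(frozen=True)
class IntegratorControls:
    eps: float = 1e-7            # shooting offset along the unit eigenvector
    tol_node: float = 1e-8       # equilibrium-ball radius for node targets
    tol_spiral: float = 1e-6     # larger ball for spiral targets
    rtol: float = 1e-10
    atol: float = 1e-12
    xi_span: float = 5000.0
    n_samples: int = 4000        # uniform resampling of the dense solution


def desingularised_rhs(state, model: ModelSpec, c: float):
    """Right-hand side (du/dxi, dp/dxi) = (p, -c p - D(u) R(u))."""
    u, p = (state.u, state.p) if isinstance(state, PlanarState) else state
    return (p, -c * p - model.D(u) * model.R(u))


def singular_rhs(state, model: ModelSpec, c: float, wall_tol: float = 1e-8):
    """Right-hand side of the singular (z-parametrised) system; only valid
    away from the walls, used as an oracle cross-check."""
    u, p = (state.u, state.p) if isinstance(state, PlanarState) else state
    d = model.D(u)
    if abs(d) < wall_tol:
        raise WallSingularityError(f"D(u)={d:g} at u={u:g} is inside the wall tolerance")
    return (p / d, (-c * p - d * model.R(u)) / d)


def _eigen_data(model: ModelSpec, c: float, u0: float):
    f = float(flux_derivative_F(model.D, model.R, u0))
    disc = complex(c * c - 4.0 * f)
    sq = np.sqrt(disc)
    lam_p = (-c + sq) / 2.0
    lam_m = (-c - sq) / 2.0
    return f, lam_p, lam_m


def find_equilibria(model: ModelSpec, c: float) -> list[EquilibriumInfo]:
    """The four equilibria (0,0), (alpha,0), (beta,0), (1,0) with eigenvalues
    lambda_pm = (-c pm sqrt(c^2 - 4 F(u)))/2 and eigenvectors (1, lambda_pm)."""
    regime = diffusivity_roots(model.D)
    if regime.label != "sign_changing":
        raise ValueError("four-equilibrium structure requires sign-changing diffusivity")
    labels = {"(0,0)": 0.0, "(alpha,0)": regime.alpha, "(beta,0)": regime.beta, "(1,0)": 1.0}
    out = []
    for label, u0 in labels.items():
        _, lam_p, lam_m = _eigen_data(model, c, u0)
        # roundoff guard: at the node/spiral boundary (disc = 0) the sqrt
        # picks up a spurious imaginary part of order sqrt(machine eps)
        if abs(lam_p.imag) > 1e-7 * max(1.0, abs(lam_p)):
            cls = "stable_spiral"
        elif lam_p.real > 0 > lam_m.real:
            cls = "saddle"
        else:
            cls = "stable_node"
        out.append(
            EquilibriumInfo(
                label=label,
                u=u0,
                eigenvalues=(lam_p, lam_m),
                eigenvectors=((1.0, lam_p), (1.0, lam_m)),
                classification=cls,
            )
        )
    return out


def _equilibrium(model, c, label) -> EquilibriumInfo:
    for eq in find_equilibria(model, c):
        if eq.label == label:
            return eq
    raise KeyError(label)


def check_slope_ordering(model: ModelSpec, c: float, point: str) -> bool:
    """True iff the slope of the relevant eigenvector (lambda_+) lies below
    the nullcline slope chi(u) = -F(u)/c at the named equilibrium — the
    geometric fact that pins the connecting orbits inside the invariant
    regions."""
    eq = _equilibrium(model, c, point)
    lam_p = eq.eigenvalues[0]
    if abs(lam_p.imag) > 1e-7 * max(1.0, abs(lam_p)):
        return False  # complex eigenvalues: no real slope to compare
    chi = -float(flux_derivative_F(model.D, model.R, eq.u)) / c
    return lam_p.real - chi < 0


def verify_invariant_region(
    model: ModelSpec, c: float, region: RegionSpec, n_samples: int = 2001
) -> bool:
    """Sampled check of the line-boundary inflow inequality
    mu (mu + c) <= -D(u) R(u) / (u - anchor) on the region's u-interval."""
    regime = diffusivity_roots(model.D)
    alpha, beta = regime.alpha, regime.beta
    if region.name == "R1":
        lo, hi = 0.0, alpha
    else:
        lo, hi = alpha, 1.0
    u = np.linspace(lo, hi, n_samples + 2)[1:-1]  # open interval
    rhs = -model.D(u) * model.R(u) / (u - region.anchor)
    lhs = region.mu * (region.mu + c)
    return bool(np.all(lhs <= rhs + 1e-13))


def default_regions(model: ModelSpec, c: float) -> list[RegionSpec]:
    """The Poincare–Bendixson regions with the proof's slope mu = -c/2."""
    beta = diffusivity_roots(model.D).beta
    return [
        RegionSpec("R1", -c / 2.0, 0.0),
        RegionSpec("R2", -c / 2.0, beta),
        RegionSpec("R3", -c / 2.0, beta),
    ]


def shoot_manifold(
    model: ModelSpec,
    c: float,
    from_label: str,
    direction_sign: int,
    controls: IntegratorControls = IntegratorControls(),
) -> Orbit:
    """Integrate the desingularised flow from a point displaced eps along the
    unstable eigenvector of a saddle, until it lands in a ball around another
    equilibrium (success) or leaves the strip u in [-0.1, 1.1] (failure).

    ``direction_sign`` chooses the side of the manifold: +1 moves towards
    increasing u, -1 towards decreasing u.
    """
    equilibria = find_equilibria(model, c)
    origin = next(eq for eq in equilibria if eq.label == from_label)
    if origin.classification != "saddle":
        raise ValueError(f"{from_label} is a {origin.classification}, not a saddle")
    lam_p = origin.eigenvalues[0].real
    vec = np.array([1.0, lam_p])
    vec /= np.linalg.norm(vec)
    y0 = np.array([origin.u, 0.0, 0.0]) + direction_sign * controls.eps * np.append(vec, 0.0)

    targets = [eq for eq in equilibria if eq.label != from_label]

    def rhs(_xi, y):
        u, p = y[0], y[1]
        du, dp = desingularised_rhs((u, p), model, c)
        return (du, dp, model.D(u))

    events = []
    for eq in targets:
        tol = controls.tol_spiral if eq.classification == "stable_spiral" else controls.tol_node

        def hit(_xi, y, u0=eq.u, tol=tol):
            return math.hypot(y[0] - u0, y[1]) - tol

        hit.terminal = True
        events.append(hit)

    def escape_hi(_xi, y):
        return y[0] - 1.1

    def escape_lo(_xi, y):
        return y[0] + 0.1

    escape_hi.terminal = True
    escape_lo.terminal = True
    events += [escape_hi, escape_lo]

    sol = solve_ivp(
        rhs,
        (0.0, controls.xi_span),
        y0,
        method="RK45",
        rtol=controls.rtol,
        atol=controls.atol,
        events=events,
        dense_output=True,
    )
    target_label = None
    for eq, hits in zip(targets, sol.t_events[: len(targets)]):
        if hits.size:
            target_label = eq.label
    if target_label is None:
        if any(ev.size for ev in sol.t_events[len(targets):]):
            raise ShootingError(f"orbit from {from_label} left the strip u in [-0.1, 1.1]")
        raise ShootingError(f"orbit from {from_label} did not converge within the xi span")

    xi = np.linspace(sol.t[0], sol.t[-1], controls.n_samples)
    y = sol.sol(xi)
    return Orbit(
        xi=xi,
        u=y[0],
        p=y[1],
        z=y[2],
        origin_label=from_label,
        target_label=target_label,
        c=c,
    )


def construct_wave_orbits(
    model: ModelSpec, c: float, controls: IntegratorControls = IntegratorControls()
) -> tuple[Orbit, Orbit, Orbit]:
    """The three heteroclinics (1,0)->(beta,0), (alpha,0)->(beta,0) and
    (alpha,0)->(0,0) of the desingularised flow."""
    upper = shoot_manifold(model, c, "(1,0)", -1, controls)
    middle = shoot_manifold(model, c, "(alpha,0)", +1, controls)
    lower = shoot_manifold(model, c, "(alpha,0)", -1, controls)
    for orbit, want in ((upper, "(beta,0)"), (middle, "(beta,0)"), (lower, "(0,0)")):
        if orbit.target_label != want:
            raise ShootingError(
                f"orbit from {orbit.origin_label} hit {orbit.target_label}, expected {want}"
            )
    return upper, middle, lower


def assemble_wave(
    orbits: tuple[Orbit, Orbit, Orbit],
    model: ModelSpec,
    c: float,
    anchor: float | None = None,
) -> TravellingWaveProfile:
    """Concatenate the three desingularised heteroclinics into the wave u(z).

    The middle orbit (alpha,0)->(beta,0) runs through the backward-diffusion
    interval where the xi-parametrisation is orientation-reversed, so its
    sample order is flipped (it becomes (beta,0)->(alpha,0) in z). Each
    orbit carries z from the augmented integration dz/dxi = D(u); segments
    are translated to join continuously at the holes, and the profile is
    anchored so that u(0) = anchor (default 1/2, or alpha/2 when
    alpha <= 1/2 so the anchor stays interior to the last segment).
    """
    upper, middle, lower = orbits
    if (upper.origin_label, upper.target_label) != ("(1,0)", "(beta,0)") or (
        middle.origin_label,
        middle.target_label,
    ) != ("(alpha,0)", "(beta,0)") or (lower.origin_label, lower.target_label) != (
        "(alpha,0)",
        "(0,0)",
    ):
        raise ValueError("orbits must connect (1,0)->(beta,0), (alpha,0)->(beta,0), (alpha,0)->(0,0)")

    regime = diffusivity_roots(model.D)
    alpha = regime.alpha

    # Interior zeros of p on the monotone segments contradict monotonicity.
    for orbit, name in ((upper, "upper"), (middle, "middle")):
        interior = orbit.p[50:-50]
        if interior.size and np.any(np.abs(interior) < 1e-13):
            raise ShootingError(f"{name} segment has p = 0 at an interior point")

    segments = []
    # (1,0)->(beta,0): D>0, z increases with xi.
    segments.append((upper.z, upper.u, upper.p))
    # (alpha,0)->(beta,0): D<0 on (alpha,beta) so z decreases with xi;
    # flipping the sample order yields the (beta,0)->(alpha,0) leg in z.
    segments.append((middle.z[::-1], middle.u[::-1], middle.p[::-1]))
    # (alpha,0)->(0,0): D>0, z increases with xi.
    segments.append((lower.z, lower.u, lower.p))

    z_parts, u_parts, p_parts = [], [], []
    offset = 0.0
    for k, (z, u, p) in enumerate(segments):
        z = z - z[0] + offset
        offset = z[-1]
        if k > 0:  # drop the duplicated hole sample
            z, u, p = z[1:], u[1:], p[1:]
        z_parts.append(z)
        u_parts.append(u)
        p_parts.append(p)
    z_all = np.concatenate(z_parts)
    u_all = np.concatenate(u_parts)
    p_all = np.concatenate(p_parts)

    # strictly increasing z for interpolation (guard against roundoff ties)
    keep = np.concatenate(([True], np.diff(z_all) > 0))
    z_all, u_all, p_all = z_all[keep], u_all[keep], p_all[keep]

    if anchor is None:
        anchor = 0.5 if alpha >= 0.5 else alpha / 2.0
    # anchor lies on the final (monotone-in-z) stretch below alpha
    tail = u_all <= alpha + 1e-9
    z_tail, u_tail = z_all[tail], u_all[tail]
    # u decreases along z on the tail until any oscillation; use first crossing
    cross = np.nonzero((u_tail[:-1] >= anchor) & (u_tail[1:] < anchor))[0]
    if cross.size:
        i = cross[0]
        frac = (u_tail[i] - anchor) / (u_tail[i] - u_tail[i + 1])
        z0 = z_tail[i] + frac * (z_tail[i + 1] - z_tail[i])
    else:
        z0 = z_all[len(z_all) // 2]
    return TravellingWaveProfile(z=z_all - z0, u=u_all, p=p_all, c=c)


def count_vertical_tangents(orbit, jitter_tol: float = 1e-9) -> int:
    """Number of interior sign changes of the tangent's u-component along a
    sampled curve (crossings of du through zero). Zero for the monotone
    wave; at least one for a spiral tail."""
    u = orbit.u if hasattr(orbit, "u") else np.asarray(orbit)
    du = np.diff(u)
    scale = np.max(np.abs(du)) if du.size else 0.0
    if scale == 0.0:
        return 0
    signs = np.sign(du[np.abs(du) > jitter_tol * scale])
    if signs.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(signs) != 0))


def wave_residual(
    profile: TravellingWaveProfile,
    model: ModelSpec,
    exclude_radius: float = 0.02,
) -> np.ndarray:
    """Finite-difference residual of (D(u) u')' + c u' + R(u) = 0 on a
    uniform z-grid, masked (NaN) near the holes where D(u) ~ 0."""
    z = np.linspace(profile.z[0], profile.z[-1], 4 * profile.z.size)
    u = profile.interpolant()(z)
    dz = z[1] - z[0]
    du = np.gradient(u, dz)
    flux = model.D(u) * du
    res = np.gradient(flux, dz) + profile.c * du + model.R(u)
    regime = diffusivity_roots(model.D)
    mask = (np.abs(u - regime.alpha) < exclude_radius) | (np.abs(u - regime.beta) < exclude_radius)
    res[mask] = np.nan
    # endpoints of the finite profile are one-sided differences; mask them too
    res[:2] = np.nan
    res[-2:] = np.nan
    return res
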