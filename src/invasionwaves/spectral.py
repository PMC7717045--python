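"""Asymptotic spectra of the linearisation about the travelling wave.

Linearising U = u_hat(z) + q about the wave and desingularising with the
same stretched variable xi gives a first-order system (d/dxi - A(xi; L)) = 0
in (q, s), s := d(D(u_hat) q)/dz. The essential and absolute spectra are set
by the constant asymptotic matrices at z -> +/-inf, where the model has a
Fisher--KPP imprint (D > 0 at both rest states). The rightmost point of the
absolute spectrum at +inf,

    K_+ = -c^2 / (4 D(0)) + R'(0),

crosses zero exactly at the minimum wave speed c* = 2 sqrt(R'(0) D(0)):
slower waves are absolutely unstable (no exponential weight can move the
essential spectrum into the left half plane); for c >= c* the one-sided
weight nu = c/(2 D(0)) shifts it furthest left, down to K_+.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import ModelSpec, min_wave_speed

__all__ = [
    "AsymptoticEnd",
    "SpectrumReport",
    "LinearisationState",
    "asymptotic_ends",
    "spatial_eigenvalues",
    "dispersion_curve",
    "absolute_spectrum_bounds",
    "weighted_intersections",
    "admissible_weight_interval",
    "ideal_weight",
    "classify_stability",
    "eigenproblem_rhs",
    "theta_rate",
]


@dataclass(frozen=True)
class AsymptoticEnd:
    """Far-field data at one end of the wave: D and R' at the rest state."""

    end_label: str     # "+inf" (u -> 0) or "-inf" (u -> 1)
    d_value: float
    r_prime: float


@dataclass(frozen=True)
class SpectrumReport:
    k_plus: float
    k_minus: float
    ideal_weight: float
    weight_interval: tuple[float, float] | None
    verdict: str       # absolutely_unstable | weight_stabilisable


@dataclass(frozen=True)
class LinearisationState:
    q: float
    s: float

    @property
    def theta(self) -> float:
        return math.atan2(self.s, self.q)


def asymptotic_ends(model: ModelSpec) -> tuple[AsymptoticEnd, AsymptoticEnd]:
    """(+inf, -inf) far-field data for a wave connecting 1 (left) to 0."""
    plus = AsymptoticEnd("+inf", float(model.D(0.0)), float(model.R.derivative(0.0)))
    minus = AsymptoticEnd("-inf", float(model.D(1.0)), float(model.R.derivative(1.0)))
    return plus, minus


def spatial_eigenvalues(end: AsymptoticEnd, c: float, Lambda: complex) -> tuple[complex, complex]:
    """The two spatial eigenvalues mu = (-c +/- sqrt(c^2 + 4 d (L - r')))/2
    of the asymptotic matrix, principal branch."""
    sq = np.sqrt(complex(c * c + 4.0 * end.d_value * (Lambda - end.r_prime)))
    return ((-c + sq) / 2.0, (-c - sq) / 2.0)


def dispersion_curve(end: AsymptoticEnd, c: float, k_values) -> np.ndarray:
    """Boundary of the unweighted essential spectrum contributed by one end:
    the left-opening parabola Lambda(k) = -d k^2 + i c k + r'."""
    k = np.asarray(k_values, dtype=float)
    return -end.d_value * k**2 + 1j * c * k + end.r_prime


def absolute_spectrum_bounds(model: ModelSpec, c: float) -> tuple[float, float]:
    """Rightmost points (K_+, K_-) of the absolute spectra at +/-inf."""
    plus, minus = asymptotic_ends(model)
    k_plus = -c * c / (4.0 * plus.d_value) + plus.r_prime
    k_minus = -c * c / (4.0 * minus.d_value) + minus.r_prime
    return k_plus, k_minus


def weighted_intersections(model: ModelSpec, c: float, nu: float) -> tuple[float, float]:
    """Real-axis intersections (K_+^nu, K_-^nu) of the weighted dispersion
    parabolas, K_pm^nu = D nu^2 - c nu + R' evaluated with each end's data."""
    plus, minus = asymptotic_ends(model)
    k_p = plus.d_value * nu * nu - c * nu + plus.r_prime
    k_m = minus.d_value * nu * nu - c * nu + minus.r_prime
    return k_p, k_m


def admissible_weight_interval(model: ModelSpec, c: float) -> tuple[float, float] | None:
    """Open interval of weights nu with K_+^nu < 0: the roots of
    D(0) nu^2 - c nu + R'(0), i.e. (c -/+ sqrt(c^2 - c*^2)) / (2 D(0)).

    Empty (None) for c < c*; degenerates to a point at c = c*.
    """
    plus, _ = asymptotic_ends(model)
    disc = c * c - 4.0 * plus.d_value * plus.r_prime
    if disc < 0:
        if disc > -1e-12 * max(1.0, c * c):  # double root blurred by roundoff
            disc = 0.0
        else:
            return None
    sq = math.sqrt(disc)
    return ((c - sq) / (2.0 * plus.d_value), (c + sq) / (2.0 * plus.d_value))


def ideal_weight(model: ModelSpec, c: float) -> float:
    """nu = c / (2 D(0)): the one-sided weight shifting the rightmost
    essential-spectrum boundary furthest left (down to K_+)."""
    plus, _ = asymptotic_ends(model)
    if plus.d_value <= 0:
        raise ValueError("ideal weight requires D(0) > 0")
    return c / (2.0 * plus.d_value)


def classify_stability(model: ModelSpec, c: float) -> SpectrumReport:
    """Absolute-stability verdict: weight_stabilisable iff K_+ <= 0,
    equivalently c >= c* (the origin itself is admitted)."""
    if c <= 0:
        raise ValueError("verdict defined for positive speeds")
    k_plus, k_minus = absolute_spectrum_bounds(model, c)
    # roundoff guard so that c = c* (where K_+ = 0 analytically) lands on
    # the inclusive stabilisable side
    tol = 1e-14 * max(1.0, abs(model.R.derivative(0.0)))
    verdict = "weight_stabilisable" if k_plus <= tol else "absolutely_unstable"
    return SpectrumReport(
        k_plus=k_plus,
        k_minus=k_minus,
        ideal_weight=ideal_weight(model, c),
        weight_interval=admissible_weight_interval(model, c),
        verdict=verdict,
    )


def _wave_dudz(u: float, p: float, model: ModelSpec, wall_tol: float = 1e-10) -> float:
    """du/dz = p / D(u) along the wave, with the removable 0/0 limit at the
    holes taken from the local eigen-data (p ~ lam (u - u0), D ~ D'(u0)(u - u0))."""
    d = float(model.D(u))
    if abs(d) > wall_tol:
        return p / d
    from .model import diffusivity_roots, flux_derivative_F

    regime = diffusivity_roots(model.D)
    hole = regime.alpha if abs(u - regime.alpha) < abs(u - regime.beta) else regime.beta
    dprime = float(model.D.derivative(hole))
    # along the connecting orbit p/(u - hole) tends to the relevant Jacobian
    # eigenvalue; the finite slope at the hole is that eigenvalue over D'
    f = float(flux_derivative_F(model.D, model.R, hole))
    # eigenvalue with the sign matching the local p/(u-hole) ratio
    lam = p / (u - hole) if u != hole else math.copysign(math.sqrt(abs(f)), -1.0)
    return lam / dprime


def eigenproblem_rhs(
    state: LinearisationState | tuple[float, float],
    wave_point: tuple[float, float],
    model: ModelSpec,
    c: float,
    Lambda: complex,
):
    """Right-hand side A(xi; Lambda) (q, s)^T of the desingularised
    eigenvalue system at a point (u, p) of the wave.

    The matrix is [[-B, 1], [c B + D(u)(Lambda - R'(u)), -c]] with
    B = D'(u) du/dz evaluated through the orbit's p-component.
    """
    q, s = (state.q, state.s) if isinstance(state, LinearisationState) else state
    u, p = wave_point
    b = float(model.D.derivative(u)) * _wave_dudz(u, p, model)
    d = float(model.D(u))
    rp = float(model.R.derivative(u))
    dq = -b * q + s
    ds = (c * b + d * (Lambda - rp)) * q - c * s
    return (dq, ds)


def theta_rate(
    state: LinearisationState | tuple[float, float],
    wave_point: tuple[float, float],
    model: ModelSpec,
    c: float,
    Lambda: complex,
) -> float:
    """Rotation rate of the (q, s) solution line through the vertical
    q = 0, oriented so that crossings count positively: equals +1 at q = 0
    for every Lambda, which is what makes the vertical-tangent count a
    Sturm-type eigenvalue counter."""
    q, s = (state.q, state.s) if isinstance(state, LinearisationState) else state
    dq, ds = eigenproblem_rhs((q, s), wave_point, model, c, Lambda)
    return float((s * dq - q * ds).real / (q * q + s * s))


def sample_dispersion(model: ModelSpec, c: float, k_values) -> "np.ndarray":
    """Both dispersion curves stacked as columns (k, ReL+, ImL+, ReL-, ImL-)."""
    plus, minus = asymptotic_ends(model)
    lp = dispersion_curve(plus, c, k_values)
    lm = dispersion_curve(minus, c, k_values)
    k = np.asarray(k_values, dtype=float)
    return np.column_stack([k, lp.real, lp.imag, lm.real, lm.imag])
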