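"""Diffusivity and kinetic functions for the invasion model, with their roots
and closed-form wave-speed thresholds.

The continuum model is the nonlinear diffusion--reaction equation

    U_t = (D(U) U_x)_x + R(U),

where ``U`` is the agent density. The two-rate diffusivity

    D(U) = D_i (1 - 4U + 3U^2) + D_g (4U - 3U^2)

arises as the mean-field limit of a lattice exclusion process in which
isolated agents (both nearest neighbours vacant) diffuse at rate ``D_i`` and
grouped agents at rate ``D_g``. When ``D_i > 4 D_g`` the diffusivity is
convex and negative on an interior interval (alpha, beta) -- aggregation
makes the equation locally backward-parabolic there. The kinetic term is
logistic, ``R(U) = lambda U (1 - U)``, in the equal-proliferation,
no-death reduction of the general birth/death kinetics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np
import yaml

__all__ = [
    "TwoRateDiffusivity",
    "PolynomialDiffusivity",
    "LogisticKinetic",
    "GeneralKinetic",
    "SignRegime",
    "ModelSpec",
    "eval_diffusivity",
    "eval_diffusivity_derivative",
    "eval_kinetic",
    "diffusivity_roots",
    "min_wave_speed",
    "beta_node_threshold",
    "positive_case_speed_bounds",
    "flux_derivative_F",
    "model_from_config",
    "model_to_config",
]


@dataclass(frozen=True)
class TwoRateDiffusivity:
    """Quadratic diffusivity of the isolated/grouped two-population model.

    ``D(u) = d_i (1 - 4u + 3u^2) + d_g (4u - 3u^2)`` so that ``D(0) = d_i``
    (a lone agent is isolated) and ``D(1) = d_g`` (a full lattice is all
    grouped agents).
    """

    d_i: float
    d_g: float

    def __post_init__(self) -> None:
        if self.d_i < 0 or self.d_g < 0:
            raise ValueError("diffusivities must be nonnegative")

    @property
    def coefficients(self) -> tuple[float, float, float]:
        """Ascending polynomial coefficients (c0, c1, c2)."""
        return (self.d_i, 4.0 * (self.d_g - self.d_i), 3.0 * (self.d_i - self.d_g))

    def __call__(self, u):
        return self.d_i * (1.0 - 4.0 * u + 3.0 * u * u) + self.d_g * (4.0 * u - 3.0 * u * u)

    def derivative(self, u):
        return (6.0 * u - 4.0) * (self.d_i - self.d_g)


@dataclass(frozen=True)
class PolynomialDiffusivity:
    """General polynomial diffusivity, coefficients in ascending order."""

    coefficients: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "coefficients", tuple(float(c) for c in self.coefficients))

    @classmethod
    def from_roots(cls, *roots: float, scale: float = 1.0) -> "PolynomialDiffusivity":
        coeffs = scale * np.polynomial.polynomial.polyfromroots(roots)
        return cls(tuple(coeffs))

    def __call__(self, u):
        return np.polynomial.polynomial.polyval(u, np.asarray(self.coefficients))

    def derivative(self, u):
        dcoef = np.polynomial.polynomial.polyder(np.asarray(self.coefficients))
        return np.polynomial.polynomial.polyval(u, dcoef)


Diffusivity = Union[TwoRateDiffusivity, PolynomialDiffusivity]


@dataclass(frozen=True)
class LogisticKinetic:
    """Logistic growth ``R(u) = lam * u * (1 - u)`` (equal proliferation,
    no death)."""

    lam: float

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("proliferation rate must be nonnegative")

    def __call__(self, u):
        return self.lam * u * (1.0 - u)

    def derivative(self, u):
        return self.lam * (1.0 - 2.0 * u)


@dataclass(frozen=True)
class GeneralKinetic:
    """Type-dependent birth/death kinetics.

    ``R(u) = lam_g u (1-u) + (lam_i - lam_g - k_i + k_g) u (1-u)^2 - k_g u``.
    Reduces to :class:`LogisticKinetic` when ``lam_i == lam_g`` and both
    death rates vanish.
    """

    lam_i: float
    lam_g: float
    k_i: float = 0.0
    k_g: float = 0.0

    def __call__(self, u):
        a = self.lam_i - self.lam_g - self.k_i + self.k_g
        return self.lam_g * u * (1.0 - u) + a * u * (1.0 - u) ** 2 - self.k_g * u

    def derivative(self, u):
        a = self.lam_i - self.lam_g - self.k_i + self.k_g
        return (
            self.lam_g * (1.0 - 2.0 * u)
            + a * ((1.0 - u) ** 2 - 2.0 * u * (1.0 - u))
            - self.k_g
        )


Kinetic = Union[LogisticKinetic, GeneralKinetic]


@dataclass(frozen=True)
class SignRegime:
    """Sign classification of a diffusivity on [0, 1].

    ``sign_changing`` carries the two roots ``alpha < beta`` where D
    vanishes; ``degenerate`` is the double-root case; ``positive_definite``
    has no root in [0, 1].
    """

    label: str
    alpha: float | None = None
    beta: float | None = None


@dataclass(frozen=True)
class ModelSpec:
    """The (D, R) pair defining one instance of the continuum model."""

    diffusivity: Diffusivity
    kinetic: Kinetic

    @property
    def D(self) -> Diffusivity:
        return self.diffusivity

    @property
    def R(self) -> Kinetic:
        return self.kinetic


def eval_diffusivity(diff: Diffusivity, u):
    """Evaluate D(u); u may lie outside [0, 1] (solvers overshoot)."""
    return diff(u)


def eval_diffusivity_derivative(diff: Diffusivity, u):
    """Exact polynomial derivative D'(u)."""
    return diff.derivative(u)


def eval_kinetic(kin: Kinetic, u):
    """Evaluate R(u)."""
    return kin(u)


def diffusivity_roots(diff: Diffusivity) -> SignRegime:
    """Classify the sign of D on [0, 1] and locate its roots.

    For the two-rate form the roots have the closed form
    ``2/3 -+ sqrt(d_i^2 + 4 d_g^2 - 5 d_i d_g) / (3 (d_i - d_g))`` and the
    sign-changing regime is exactly ``d_i > 4 d_g``.
    """
    if isinstance(diff, TwoRateDiffusivity):
        d_i, d_g = diff.d_i, diff.d_g
        if d_i < 4.0 * d_g:
            return SignRegime("positive_definite")
        if d_i == 4.0 * d_g:
            return SignRegime("degenerate", alpha=2.0 / 3.0, beta=2.0 / 3.0)
        disc = d_i * d_i + 4.0 * d_g * d_g - 5.0 * d_i * d_g
        half_width = math.sqrt(disc) / (3.0 * (d_i - d_g))
        return SignRegime("sign_changing", alpha=2.0 / 3.0 - half_width, beta=2.0 / 3.0 + half_width)

    # General polynomial: closed form up to degree 2, companion matrix above.
    coeffs = np.trim_zeros(np.asarray(diff.coefficients, dtype=float), "b")
    if coeffs.size <= 1:
        return SignRegime("positive_definite" if (coeffs.size and coeffs[0] > 0) else "degenerate")
    if coeffs.size == 2:
        roots = np.array([-coeffs[0] / coeffs[1]])
    elif coeffs.size == 3:
        c0, c1, c2 = coeffs
        disc = c1 * c1 - 4.0 * c0 * c2
        if disc < 0:
            roots = np.array([])
        else:
            sq = math.sqrt(disc)
            roots = np.sort(np.array([(-c1 - sq) / (2 * c2), (-c1 + sq) / (2 * c2)]))
    else:
        rr = np.polynomial.polynomial.polyroots(coeffs)
        roots = np.sort(np.real(rr[np.abs(np.imag(rr)) < 1e-12]))
    interior = roots[(roots >= 0.0) & (roots <= 1.0)]
    # Keep only roots where the sign actually changes (odd multiplicity).
    if interior.size == 0:
        label = "positive_definite" if diff(0.5) > 0 else "degenerate"
        return SignRegime(label)
    if interior.size == 1:
        return SignRegime("degenerate", alpha=float(interior[0]), beta=float(interior[0]))
    return SignRegime("sign_changing", alpha=float(interior[0]), beta=float(interior[-1]))


def min_wave_speed(diff: Diffusivity, kin: Kinetic) -> float:
    """Minimum speed ``c* = 2 sqrt(R'(0) D(0))`` of monotone nonnegative waves.

    This is the linear-spreading (pulled-front) value set by the behaviour
    near the invaded state u = 0; for the two-rate model it depends only on
    the isolated-agent diffusivity.
    """
    d0 = float(diff(0.0))
    if d0 <= 0:
        raise ValueError("minimum wave speed requires D(0) > 0")
    r0 = float(kin.derivative(0.0))
    return 2.0 * math.sqrt(r0 * d0)


def beta_node_threshold(diff: Diffusivity, kin: Kinetic) -> float:
    """Speed ``2 sqrt(D'(beta) R(beta))`` above which the upper-root
    equilibrium (beta, 0) of the desingularised flow is a stable node
    rather than a spiral.

    Below this speed the hole in the wall at u = beta cannot be crossed by
    a smooth wave.
    """
    regime = diffusivity_roots(diff)
    if regime.label != "sign_changing":
        raise ValueError("no sign-changing upper root beta in (0, 1)")
    beta = regime.beta
    dprime = float(diff.derivative(beta))
    if dprime <= 0:
        raise ValueError("upper root must have D'(beta) > 0")
    return 2.0 * math.sqrt(dprime * float(kin(beta)))


def positive_case_speed_bounds(
    diff: Diffusivity, kin: Kinetic, grid_resolution: int = 10_000
) -> tuple[float, float]:
    """Bracket (S2, S1) for the minimum wave speed when D > 0 on [0, 1].

    ``S2 = 2 sqrt(R'(0) D(0))`` is the linear (node) threshold at the
    origin; ``S1 = sup_u 2 sqrt(D(u) R(u) / u)`` is the invariant-region
    sufficient bound. The supremum is located on a dense grid and polished
    by bounded scalar minimisation (tolerance 1e-10 in u).
    """
    regime = diffusivity_roots(diff)
    if regime.label == "sign_changing":
        raise ValueError("speed bracket applies to positive-definite diffusivity only")
    s2 = min_wave_speed(diff, kin)

    def neg_objective(u):
        # D(u) R(u) / u, continuously extended by R'(0) D(0) at u = 0.
        return -np.where(u > 0, diff(u) * kin(u) / np.where(u > 0, u, 1.0), diff(0.0) * kin.derivative(0.0))

    from scipy.optimize import minimize_scalar

    grid = np.linspace(0.0, 1.0, grid_resolution)
    vals = neg_objective(grid)
    j = int(np.argmin(vals))
    lo = grid[max(j - 1, 0)]
    hi = grid[min(j + 1, grid_resolution - 1)]
    res = minimize_scalar(neg_objective, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10})
    best = min(float(res.fun), float(vals[j]))
    s1 = 2.0 * math.sqrt(-best)
    return s2, max(s1, s2)


def flux_derivative_F(diff: Diffusivity, kin: Kinetic, u):
    """F(u) = d/du [D(u) R(u)] = D'(u) R(u) + D(u) R'(u)."""
    return diff.derivative(u) * kin(u) + diff(u) * kin.derivative(u)


# -- plain-text config round trip -------------------------------------------

def model_to_config(model: ModelSpec) -> dict:
    """Serialise a model to a plain YAML-compatible mapping."""
    out: dict = {}
    d = model.diffusivity
    if isinstance(d, TwoRateDiffusivity):
        out["d_i"] = d.d_i
        out["d_g"] = d.d_g
    else:
        out["poly_coeffs"] = list(d.coefficients)
    k = model.kinetic
    if isinstance(k, LogisticKinetic):
        out["lam"] = k.lam
    else:
        out.update({"lam_i": k.lam_i, "lam_g": k.lam_g, "k_i": k.k_i, "k_g": k.k_g})
    return out


def model_from_config(config) -> ModelSpec:
    """Build a model from a mapping, a YAML string or a file path."""
    if isinstance(config, (str, bytes)):
        try:
            with open(config) as fh:
                config = yaml.safe_load(fh)
        except (FileNotFoundError, OSError):
            config = yaml.safe_load(config)
    if "poly_coeffs" in config:
        diff: Diffusivity = PolynomialDiffusivity(tuple(config["poly_coeffs"]))
    else:
        diff = TwoRateDiffusivity(float(config["d_i"]), float(config["d_g"]))
    if "lam" in config:
        kin: Kinetic = LogisticKinetic(float(config["lam"]))
    else:
        kin = GeneralKinetic(
            float(config["lam_i"]),
            float(config["lam_g"]),
            float(config.get("k_i", 0.0)),
            float(config.get("k_g", 0.0)),
        )
    return ModelSpec(diff, kin)
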