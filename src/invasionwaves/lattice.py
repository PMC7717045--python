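"""The one-dimensional lattice exclusion process underlying the continuum
model, in two forms: the deterministic mean-field occupancy recurrence and
a stochastic agent-based realisation.

Agents live on a lattice with at most one agent per site. An agent is
*isolated* when both nearest neighbours are vacant and *grouped* otherwise;
the two classes carry their own motility, proliferation and death
probabilities per time step (P_m, P_p, P_d). The mean-field change of the
occupancy U_j in one step collects nine bracket terms: isolated-motility
transfers (triple products enforcing the vacancy of the second neighbour),
grouped-motility transfers written as all-agent transfers minus the
isolated correction, the analogous proliferation split, and the two death
terms. Taylor expansion and the diffusive limit (Delta, tau -> 0 with
Delta^2/tau fixed) turn the recurrence into the continuum PDE with
D_x = P_m^x Delta^2 / (2 tau), lambda_x = P_p^x / tau, K_x = P_d^x / tau.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "LatticeParams",
    "MeanFieldState",
    "AgentLattice",
    "ContinuumMap",
    "OccupancyError",
    "meanfield_delta",
    "meanfield_step",
    "meanfield_simulate",
    "continuum_parameters",
    "lattice_parameters",
    "stochastic_step",
    "stochastic_simulate",
    "density_profile",
]


class OccupancyError(RuntimeError):
    """Mean-field occupancy left [0, 1] (inadmissible parameters)."""


@dataclass(frozen=True)
class LatticeParams:
    p_m_i: float
    p_m_g: float
    p_p_i: float = 0.0
    p_p_g: float = 0.0
    p_d_i: float = 0.0
    p_d_g: float = 0.0
    delta: float = 1.0
    tau: float = 1.0

    def __post_init__(self) -> None:
        probs = (self.p_m_i, self.p_m_g, self.p_p_i, self.p_p_g, self.p_d_i, self.p_d_g)
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("event probabilities must lie in [0, 1]")
        if self.delta <= 0 or self.tau <= 0:
            raise ValueError("delta and tau must be positive")
        if self.p_m_i + self.p_p_i + self.p_d_i > 1 + 1e-12:
            raise ValueError("combined isolated-agent event probability exceeds 1")
        if self.p_m_g + self.p_p_g + self.p_d_g > 1 + 1e-12:
            raise ValueError("combined grouped-agent event probability exceeds 1")


@dataclass
class MeanFieldState:
    occupancy: np.ndarray
    step_index: int = 0

    @property
    def x(self) -> np.ndarray:  # convenience; site j sits at j * delta
        return np.arange(self.occupancy.size, dtype=float)


@dataclass
class AgentLattice:
    sites: np.ndarray  # int8 occupancy, exclusion enforced by construction
    rng_seed: int = 0


@dataclass(frozen=True)
class ContinuumMap:
    d_i: float
    d_g: float
    lam_i: float
    lam_g: float
    k_i: float
    k_g: float


def _delta_all(u: np.ndarray, prm: LatticeParams) -> np.ndarray:
    """Vectorised mean-field increment for every site.

    The occupancy balance is evaluated in its equivalent bond-flux form:
    every motility term is a transfer across one bond (agent at k hopping
    to a vacant neighbour, with the isolated class carrying the
    second-neighbour vacancy factor) and every proliferation term a birth
    across one bond, so interior sites reproduce the nine-bracket balance
    term for term while the transfer fluxes telescope, conserving total
    occupancy exactly when births and deaths are off. Off-lattice ghosts
    are vacant and cross-boundary transfers are dropped (an agent
    attempting to step off the lattice aborts), the discrete analogue of
    the PDE's no-flux condition and the convention of the stochastic model.
    """
    u = np.asarray(u, dtype=float)
    um1 = np.concatenate(([0.0], u[:-1]))   # U_{j-1}, vacant ghost
    up1 = np.concatenate((u[1:], [0.0]))    # U_{j+1}, vacant ghost

    # isolated-agent event weight at each site: occupied with both
    # neighbours vacant (also the target-vacancy factor for either hop)
    t_iso = u * (1.0 - um1) * (1.0 - up1)

    # net rightward motility flux across bond j -> j+1
    f_iso = 0.5 * prm.p_m_i * (t_iso[:-1] - t_iso[1:])
    f_all = 0.5 * prm.p_m_g * ((u[:-1] - u[1:]) - (t_iso[:-1] - t_iso[1:]))
    f = f_iso + f_all
    du = np.zeros_like(u)
    du[:-1] -= f
    du[1:] += f

    # births deposited across bonds into site j from each neighbour
    birth_iso = 0.5 * prm.p_p_i * (
        np.concatenate(([0.0], t_iso[:-1])) + np.concatenate((t_iso[1:], [0.0]))
    )
    all_in = um1 * (1.0 - u) + up1 * (1.0 - u)
    iso_in = (
        np.concatenate(([0.0], t_iso[:-1])) + np.concatenate((t_iso[1:], [0.0]))
    )
    birth_grp = 0.5 * prm.p_p_g * (all_in - iso_in)
    du += birth_iso + birth_grp

    # deaths: isolated and grouped classes
    du -= prm.p_d_i * t_iso + prm.p_d_g * (u - t_iso)
    return du


def meanfield_delta(state: MeanFieldState, params: LatticeParams, j: int) -> float:
    """The mean-field occupancy increment delta U_j at site j."""
    return float(_delta_all(state.occupancy, params)[j])


def meanfield_step(state: MeanFieldState, params: LatticeParams) -> MeanFieldState:
    """One synchronous update U_j <- U_j + delta U_j."""
    u = state.occupancy + _delta_all(state.occupancy, params)
    if u.min() < -1e-12 or u.max() > 1 + 1e-12:
        raise OccupancyError(
            f"occupancy left [0,1] at step {state.step_index + 1}: "
            f"range [{u.min():g}, {u.max():g}]"
        )
    return MeanFieldState(occupancy=u, step_index=state.step_index + 1)


def meanfield_simulate(
    initial: MeanFieldState,
    params: LatticeParams,
    n_steps: int,
    record_every: int = 1,
) -> list[MeanFieldState]:
    """Iterate the recurrence, recording every ``record_every`` steps
    (the initial state is always included)."""
    out = [MeanFieldState(initial.occupancy.copy(), initial.step_index)]
    state = out[0]
    for k in range(n_steps):
        state = meanfield_step(state, params)
        if (k + 1) % record_every == 0:
            out.append(MeanFieldState(state.occupancy.copy(), state.step_index))
    if out[-1].step_index != state.step_index:
        out.append(state)
    return out


def continuum_parameters(params: LatticeParams) -> ContinuumMap:
    """Finite-Delta surrogate of the diffusive-limit map."""
    f = params.delta**2 / (2.0 * params.tau)
    return ContinuumMap(
        d_i=params.p_m_i * f,
        d_g=params.p_m_g * f,
        lam_i=params.p_p_i / params.tau,
        lam_g=params.p_p_g / params.tau,
        k_i=params.p_d_i / params.tau,
        k_g=params.p_d_g / params.tau,
    )


def lattice_parameters(cont: ContinuumMap, delta: float, tau: float) -> LatticeParams:
    """Inverse map: per-step probabilities realising given continuum rates."""
    f = 2.0 * tau / delta**2
    return LatticeParams(
        p_m_i=cont.d_i * f,
        p_m_g=cont.d_g * f,
        p_p_i=cont.lam_i * tau,
        p_p_g=cont.lam_g * tau,
        p_d_i=cont.k_i * tau,
        p_d_g=cont.k_g * tau,
        delta=delta,
        tau=tau,
    )


@njit(cache=True)
def _stochastic_step_kernel(sites, order, uniforms, p_m_i, p_m_g, p_p_i, p_p_g, p_d_i, p_d_g):
    """Random-sequential update of one time step. ``order`` is a shuffled
    list of the initially occupied sites; each agent classifies itself at
    action time, then attempts move, proliferation and death in turn.
    Moves and births aborted on occupied or off-lattice targets."""
    n = sites.size
    for a in range(order.size):
        j = order[a]
        # classification at action time (off-lattice counts as vacant)
        left = sites[j - 1] if j > 0 else 0
        right = sites[j + 1] if j < n - 1 else 0
        isolated = left == 0 and right == 0
        p_m = p_m_i if isolated else p_m_g
        p_p = p_p_i if isolated else p_p_g
        p_d = p_d_i if isolated else p_d_g
        pos = j
        if uniforms[a, 0] < p_m:
            tgt = pos + (1 if uniforms[a, 1] < 0.5 else -1)
            if 0 <= tgt < n and sites[tgt] == 0:
                sites[pos] = 0
                sites[tgt] = 1
                pos = tgt
        if uniforms[a, 2] < p_p:
            tgt = pos + (1 if uniforms[a, 3] < 0.5 else -1)
            if 0 <= tgt < n and sites[tgt] == 0:
                sites[tgt] = 1
        if uniforms[a, 4] < p_d:
            sites[pos] = 0
    return sites


def stochastic_step(lattice: AgentLattice, params: LatticeParams, rng: np.random.Generator) -> AgentLattice:
    """One time step of the agent-based model (random-sequential over the
    agents present at the start of the step)."""
    sites = lattice.sites.astype(np.int8).copy()
    occupied = np.flatnonzero(sites).astype(np.int64)
    order = rng.permutation(occupied)
    uniforms = rng.random((order.size, 5))
    _stochastic_step_kernel(
        sites, order, uniforms,
        params.p_m_i, params.p_m_g, params.p_p_i,
        params.p_p_g, params.p_d_i, params.p_d_g,
    )
    return AgentLattice(sites=sites, rng_seed=lattice.rng_seed)


def stochastic_simulate(
    initial_sites: np.ndarray,
    params: LatticeParams,
    n_steps: int,
    rng: np.random.Generator,
    record_every: int = 1,
) -> np.ndarray:
    """Run one replicate; returns the (n_records, n_sites) int8 occupancy
    history including the initial state."""
    sites = np.asarray(initial_sites, dtype=np.int8).copy()
    frames = [sites.copy()]
    lat = AgentLattice(sites)
    for k in range(n_steps):
        lat = stochastic_step(lat, params, rng)
        if (k + 1) % record_every == 0:
            frames.append(lat.sites.copy())
    return np.asarray(frames)


def density_profile(replicates: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Arithmetic-mean occupancy across replicate trajectories and its
    standard error (0 for a single replicate)."""
    if len(replicates) == 0:
        raise ValueError("need at least one replicate")
    stack = np.asarray(replicates, dtype=float)
    mean = stack.mean(axis=0)
    if stack.shape[0] == 1:
        return mean, np.zeros_like(mean)
    se = stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
    return mean, se
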