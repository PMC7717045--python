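"""Desingularised flow: equilibria, invariant regions, shooting, assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from invasionwaves.model import (
    LogisticKinetic,
    ModelSpec,
    TwoRateDiffusivity,
    beta_node_threshold,
    diffusivity_roots,
    flux_derivative_F,
    min_wave_speed,
)
from invasionwaves.phaseplane import (
    IntegratorControls,
    Orbit,
    PlanarState,
    RegionSpec,
    ShootingError,
    WallSingularityError,
    assemble_wave,
    check_slope_ordering,
    construct_wave_orbits,
    count_vertical_tangents,
    default_regions,
    desingularised_rhs,
    find_equilibria,
    shoot_manifold,
    singular_rhs,
    verify_invariant_region,
    wave_residual,
)

sign_changing = st.tuples(
    st.floats(0.05, 5.0), st.floats(1e-3, 0.2499), st.floats(0.05, 5.0), st.floats(0.05, 3.0)
)


def test_rhs_at_hole(aggregation_model):
    # (alpha, 0) is an equilibrium because D(alpha) = 0 kills the product term
    du, dp = desingularised_rhs(PlanarState(0.5, 0.0), aggregation_model, 0.866)
    assert (du, dp) == (0.0, pytest.approx(0.0, abs=1e-15))
    du, dp = desingularised_rhs(PlanarState(0.5, -0.1), aggregation_model, 0.866)
    assert du == -0.1
    assert dp == pytest.approx(0.0866, abs=1e-12)


def test_rhs_between_walls_pushes_up(aggregation_model):
    # D < 0 and R > 0 between the walls, so dp/dxi = -D R > 0 on p = 0
    _, dp = desingularised_rhs(PlanarState(2.0 / 3.0, 0.0), aggregation_model, 1.0)
    d = aggregation_model.D(2.0 / 3.0)
    assert d < 0
    assert dp == pytest.approx(-d * aggregation_model.R(2.0 / 3.0), rel=1e-12)
    assert dp > 0


def test_singular_rhs_orientation(aggregation_model):
    """Between the walls (D < 0) the singular flow is antiparallel to the
    desingularised flow; outside (D > 0) it is parallel."""
    c = 0.866
    for u, parallel in ((0.6, False), (0.3, True), (0.9, True)):
        state = PlanarState(u, -0.05)
        a = np.array(desingularised_rhs(state, aggregation_model, c))
        b = np.array(singular_rhs(state, aggregation_model, c))
        cosang = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
        assert cosang == pytest.approx(1.0 if parallel else -1.0, abs=1e-12)


def test_singular_rhs_errors_on_wall(aggregation_model):
    with pytest.raises(WallSingularityError):
        singular_rhs(PlanarState(0.5, 0.1), aggregation_model, 0.866)


@pytest.mark.parametrize(
    "c, expected",
    [
        (None, {"(0,0)": "stable_node", "(alpha,0)": "saddle", "(beta,0)": "stable_node", "(1,0)": "saddle"}),
        (0.4, {"(0,0)": "stable_spiral", "(alpha,0)": "saddle", "(beta,0)": "stable_node", "(1,0)": "saddle"}),
        (0.2, {"(0,0)": "stable_spiral", "(alpha,0)": "saddle", "(beta,0)": "stable_spiral", "(1,0)": "saddle"}),
    ],
)
def test_equilibrium_classification_vs_speed(aggregation_model, c_star, c, expected):
    c = c_star if c is None else c
    got = {eq.label: eq.classification for eq in find_equilibria(aggregation_model, c)}
    assert got == expected


@settings(max_examples=50, deadline=None)
@given(sign_changing)
def test_eigen_data_closed_forms(draw):
    """Eigenvalues match (-c +- sqrt(c^2 - 4F))/2 with F = (DR)' at each
    equilibrium, and eigenvectors (1, lambda) satisfy the Jacobian relation."""
    d_i, frac, lam, c = draw
    model = ModelSpec(TwoRateDiffusivity(d_i, d_i * frac), LogisticKinetic(lam))
    for eq in find_equilibria(model, c):
        f = flux_derivative_F(model.D, model.R, eq.u)
        for lam_eig, vec in zip(eq.eigenvalues, eq.eigenvectors):
            assert lam_eig**2 + c * lam_eig + f == pytest.approx(0.0, abs=1e-10)
            # Jacobian [[0, 1], [-F, -c]] acting on (1, lambda)
            jv = np.array([vec[1], -f * vec[0] - c * vec[1]])
            assert np.allclose(jv, lam_eig * np.array(vec), atol=1e-10)


def test_slope_ordering_at_all_points(aggregation_model, c_star):
    for pt in ("(1,0)", "(alpha,0)", "(0,0)", "(beta,0)"):
        assert check_slope_ordering(aggregation_model, c_star, pt)


def test_invariant_regions_hold_at_cstar(aggregation_model, c_star):
    for region in default_regions(aggregation_model, c_star):
        assert verify_invariant_region(aggregation_model, c_star, region)


def test_invariant_region_fails_below_cstar(aggregation_model, c_star):
    c = 0.5 * c_star
    region = RegionSpec("R1", -c / 2.0, 0.0)
    assert not verify_invariant_region(aggregation_model, c, region)


def test_shooting_endpoints(reference_wave):
    orbits, _ = reference_wave
    assert [(o.origin_label, o.target_label) for o in orbits] == [
        ("(1,0)", "(beta,0)"),
        ("(alpha,0)", "(beta,0)"),
        ("(alpha,0)", "(0,0)"),
    ]


def test_shooting_step_halving_consistency(aggregation_model, c_star):
    """p along the (1,0)->(beta,0) orbit at u = 0.9 is insensitive to the
    integrator tolerance (independent-resolution cross-check)."""
    a = shoot_manifold(aggregation_model, c_star, "(1,0)", -1)
    b = shoot_manifold(
        aggregation_model, c_star, "(1,0)", -1,
        IntegratorControls(rtol=5e-11, atol=5e-13),
    )
    pa = np.interp(0.9, a.u[::-1], a.p[::-1])
    pb = np.interp(0.9, b.u[::-1], b.p[::-1])
    assert pa == pytest.approx(pb, abs=1e-6)


def test_shooting_rejects_non_saddle(aggregation_model, c_star):
    with pytest.raises(ValueError):
        shoot_manifold(aggregation_model, c_star, "(0,0)", -1)


def test_assembled_wave_monotone_in_unit_interval(reference_wave):
    _, profile = reference_wave
    assert np.all(np.diff(profile.u) <= 1e-12)
    assert profile.u.min() >= 0.0
    assert profile.u.max() <= 1.0 + 1e-9
    assert profile.u[0] > 0.999
    assert profile.u[-1] < 1e-5


def test_assembled_wave_satisfies_travelling_wave_ode(reference_wave, aggregation_model):
    _, profile = reference_wave
    res = wave_residual(profile, aggregation_model)
    assert np.nanmax(np.abs(res)) < 1e-4


def test_wave_invariant_under_tolerance_halving(aggregation_model, c_star, reference_wave):
    _, p1 = reference_wave
    ctrl = IntegratorControls(rtol=5e-11, atol=5e-13)
    p2 = assemble_wave(construct_wave_orbits(aggregation_model, c_star, ctrl), aggregation_model, c_star)
    zz = np.linspace(max(p1.z[0], p2.z[0]), min(p1.z[-1], p2.z[-1]), 2000)
    assert np.max(np.abs(p1.interpolant()(zz) - p2.interpolant()(zz))) < 1e-5


def test_slow_wave_oscillates_below_zero(aggregation_model):
    """Between the node/spiral threshold and c* the lower connection
    spirals into the origin, so the tail dips below u = 0."""
    assert beta_node_threshold(aggregation_model.D, aggregation_model.R) < 0.4
    orbits = construct_wave_orbits(aggregation_model, 0.4)
    profile = assemble_wave(orbits, aggregation_model, 0.4)
    assert orbits[2].u.min() < 0.0
    assert profile.u.min() < 0.0
    assert count_vertical_tangents(orbits[2]) >= 1


def test_vertical_tangent_counts(reference_wave):
    _, profile = reference_wave
    assert count_vertical_tangents(profile) == 0
    straight = Orbit(
        xi=np.linspace(0, 1, 50),
        u=np.linspace(1, 0, 50),
        p=-np.linspace(1, 0, 50),
        z=np.linspace(0, 1, 50),
        origin_label="synthetic",
        target_label="synthetic",
        c=1.0,
    )
    assert count_vertical_tangents(straight) == 0


def test_singular_and_desingularised_trajectories_coincide(aggregation_model, c_star):
    """Away from the walls the singular (z-parametrised) flow retraces the
    desingularised orbit: direct stiff integration of the z-system from a
    point on the orbit stays on it (sup distance < 1e-5 in u-p space)."""
    from scipy.integrate import solve_ivp

    orbit = shoot_manifold(
        aggregation_model, c_star, "(alpha,0)", -1, IntegratorControls(n_samples=40000)
    )
    sel = (orbit.u > 0.1) & (orbit.u < 0.4)
    u0, p0 = orbit.u[sel][0], orbit.p[sel][0]

    def rhs(_z, y):
        return singular_rhs((y[0], y[1]), aggregation_model, c_star)

    stop = lambda _z, y: y[0] - 0.1
    stop.terminal = True
    sol = solve_ivp(rhs, (0.0, 20.0), (u0, p0), rtol=1e-10, atol=1e-12, dense_output=True,
                    events=stop)
    zs = np.linspace(0, sol.t[-1], 400)
    traj = sol.sol(zs)
    p_ref = np.interp(traj[0][::-1], orbit.u[sel][::-1], orbit.p[sel][::-1])[::-1]
    assert np.max(np.abs(traj[1] - p_ref)) < 1e-5


def test_wave_matches_pde_front(aggregation_model):
    """Late-time PDE front shape from a Heaviside start agrees with the
    phase-plane wave assembled at the measured speed (scheme-limited)."""
    from invasionwaves.pde import Grid1D, SimConfig, estimate_speed, ic_heaviside, simulate
    from invasionwaves.pipeline import compare_profiles

    grid = Grid1D(0.0, 100.0, 0.1)
    snaps, track = simulate(
        aggregation_model, ic_heaviside(grid, 40.0), grid, SimConfig(dt=0.01, t_final=60.0)
    )
    speed, _ = estimate_speed(track, t_window=(0.0, 60.0))
    profile = assemble_wave(
        construct_wave_orbits(aggregation_model, speed), aggregation_model, speed
    )
    final = snaps[-1].u
    sel = (final > 1e-8) & (final < 1 - 1e-8)
    result = compare_profiles((profile.z, profile.u), (grid.x[sel], final[sel]))
    assert result["sup_norm"] < 2e-2
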