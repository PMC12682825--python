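"""Richards water flow, nitrate convection-dispersion, mineralization and
root water uptake partitioning."""

import numpy as np
import pytest

from stopsignal import soil_dynamics as sd
from stopsignal.soils import SoilLayer, build_profile
from ._reference import explicit_infiltration


def make_state(profile, theta, conc=0.0):
    return sd.initialize_state(
        profile, np.full(profile.n_nodes, theta), np.full(profile.n_nodes, conc)
    )


def test_hydrostatic_equilibrium_is_preserved(toy_profile):
    """No-flux column with total head constant (h = H + z) stays put."""
    p = toy_profile
    H = -250.0
    h0 = H + p.node_depths
    theta0 = p.theta_of_head(h0)
    state = sd.SoilState(
        theta=theta0.copy(), head=h0.copy(),
        nitrate_mass=np.zeros(p.n_nodes), mineralizable_N=np.zeros(p.n_nodes),
        PR=p.penetration_resistance_nodes(theta0),
    )
    sd.advance_water(
        state, p, np.zeros(p.n_nodes), surface_input=0.0,
        potential_evaporation=0.0, bottom="no_flux",
    )
    assert np.max(np.abs(state.theta - theta0)) < 1e-6


def test_infiltration_matches_fine_grid_explicit_reference(sandy_hydraulics):
    """Half-day infiltration into a dry 20 cm column vs an independent
    forward-Euler solve at 8x finer resolution."""
    params = sandy_hydraulics
    profile = build_profile(
        [SoilLayer(0.0, 20.0, "sandy loam", bulk_density=1.45, organic_matter=2.0)],
        grid_dz=2.0,
    )
    theta0, q_top, t_end = 0.12, 0.5, 0.5
    state = make_state(profile, theta0)
    diag = sd.advance_water(
        state, profile, np.zeros(profile.n_nodes), surface_input=q_top,
        potential_evaporation=0.0,
        dt_total=t_end,
    )
    ref = explicit_infiltration(params, theta0, q_top, 20.0, t_end)
    ref_coarse = ref.reshape(profile.n_nodes, -1).mean(axis=1)
    assert np.max(np.abs(state.theta - ref_coarse)) < 0.02
    assert state.theta.sum() * 2.0 == pytest.approx(ref_coarse.sum() * 2.0, abs=5e-3)
    # wetting front advances monotonically: theta decreasing with depth
    assert np.all(np.diff(state.theta) <= 1e-9)
    # storage = initial + inflow - drainage
    storage = state.theta.sum() * profile.grid_dz
    expected = theta0 * 20.0 + diag["infiltration"] - diag["drainage"]
    assert storage == pytest.approx(expected, abs=1e-3)


def test_quasi_steady_state_with_sink_equal_to_inflow(toy_profile):
    p = toy_profile
    state = make_state(p, float(np.mean(p.theta_fc)))
    sink = np.zeros(p.n_nodes)
    sink[:5] = 0.2 / 5.0  # extraction near the surface, where input arrives
    kw = dict(surface_input=0.2, potential_evaporation=0.0, bottom="no_flux")
    for _ in range(15):  # spin up to quasi-steady
        sd.advance_water(state, p, sink, **kw)
    s0 = state.theta.sum() * p.grid_dz
    sd.advance_water(state, p, sink, **kw)
    assert abs(state.theta.sum() * p.grid_dz - s0) < 5e-3


def test_per_step_water_balance(toy_profile):
    p = toy_profile
    state = make_state(p, 0.15)
    diag = sd.richards_step(
        state, p, np.zeros(p.n_nodes), q_top=0.4, dt=0.05
    )
    assert abs(diag["balance_error"]) < 1e-4


def test_uptake_zero_at_wilting_point(toy_profile):
    p = toy_profile
    state = make_state(p, float(p.theta_pwp[0]))
    uptake, actual = sd.water_uptake_sink(np.full(p.n_nodes, 100.0), state, p, 0.3)
    assert actual == 0.0
    assert np.all(uptake == 0.0)


def test_uptake_splits_by_length_times_availability(toy_profile):
    p = toy_profile
    theta = np.full(p.n_nodes, p.theta_pwp[0])
    theta[2] = p.theta_fc[2]  # availability 1
    theta[5] = 0.5 * (p.theta_fc[5] + p.theta_pwp[5])  # availability 0.5
    state = sd.initialize_state(p, theta, np.zeros(p.n_nodes))
    rld = np.zeros(p.n_nodes)
    rld[2] = rld[5] = 50.0
    uptake, actual = sd.water_uptake_sink(rld, state, p, demand=0.06)
    assert actual == pytest.approx(0.06)
    assert uptake[2] / uptake[5] == pytest.approx(2.0, rel=1e-6)


def test_uptake_single_wet_node_capped_by_its_water(toy_profile):
    p = toy_profile
    theta = np.full(p.n_nodes, p.theta_pwp[0])
    theta[3] = p.theta_pwp[3] + 0.01
    state = sd.initialize_state(p, theta, np.zeros(p.n_nodes))
    rld = np.zeros(p.n_nodes)
    rld[3] = 100.0
    uptake, actual = sd.water_uptake_sink(rld, state, p, demand=1.0)
    cap = 0.01 * p.grid_dz
    assert actual == pytest.approx(cap, rel=1e-6)
    assert np.flatnonzero(uptake).tolist() == [3]


def long_profile():
    return build_profile(
        [SoilLayer(0.0, 120.0, "sandy loam", bulk_density=1.45, organic_matter=1.0)],
        grid_dz=2.0,
    )


def test_nitrate_uniform_no_flux_unchanged():
    p = long_profile()
    state = make_state(p, 0.30, conc=2.0)
    m0 = state.nitrate_mass.copy()
    diag = sd.nitrate_step(
        state, p, q_faces=np.zeros(p.n_nodes - 1), q_top=0.0, q_bot=0.0,
        uptake_N=np.zeros(p.n_nodes), dt=1.0,
    )
    assert np.allclose(state.nitrate_mass, m0, rtol=1e-12)
    assert abs(diag["closure"]) < 1e-9


def test_nitrate_pulse_advects_at_pore_velocity():
    """Center of mass of a solute pulse moves q*dt/theta under constant flux."""
    p = long_profile()
    theta = 0.30
    state = make_state(p, theta, conc=0.0)
    state.nitrate_mass[20] = 100.0
    q = 0.3
    for _ in range(4):
        sd.nitrate_step(
            state, p, q_faces=np.full(p.n_nodes - 1, q), q_top=q, q_bot=q,
            uptake_N=np.zeros(p.n_nodes), dt=1.0,
        )
    com = float((state.nitrate_mass * p.node_depths).sum() / state.nitrate_mass.sum())
    expected_shift = q * 4.0 / theta
    assert com - p.node_depths[20] == pytest.approx(expected_shift, abs=0.35)


def test_sustained_flux_leaches_nitrate_downward():
    p = long_profile()
    state = make_state(p, 0.30, conc=2.0)
    top0 = state.nitrate_mass[:10].sum()
    drained = []
    for _ in range(10):
        d = sd.nitrate_step(
            state, p, q_faces=np.full(p.n_nodes - 1, 0.5), q_top=0.5, q_bot=0.5,
            uptake_N=np.zeros(p.n_nodes), dt=1.0,
        )
        drained.append(state.cumulative_drainage_N)
        assert abs(d["closure"]) < 1e-9 * max(state.nitrate_mass.sum(), 1.0)
    assert np.all(np.diff(drained) > 0)
    assert state.nitrate_mass[:10].sum() < top0


def test_nitrate_uptake_capped_at_available_mass():
    p = long_profile()
    state = make_state(p, 0.30, conc=0.1)
    demand = np.full(p.n_nodes, 1e6)
    d = sd.nitrate_step(
        state, p, q_faces=np.zeros(p.n_nodes - 1), q_top=0.0, q_bot=0.0,
        uptake_N=demand, dt=1.0,
    )
    assert state.nitrate_mass.sum() == pytest.approx(0.0, abs=1e-9)
    assert d["uptake"] == pytest.approx(0.1 * 0.30 * 2.0 * p.n_nodes, rel=1e-9)


def test_mineralization_zero_without_organic_matter(toy_profile):
    p = toy_profile
    state = make_state(p, 0.2)
    state.mineralizable_N[:] = 0.0
    assert sd.mineralize(state, p, dt=1.0, t=0.0) == 0.0


def test_mineralization_halves_with_organic_matter():
    p = long_profile()
    s_full = make_state(p, 0.25)
    s_half = make_state(p, 0.25)
    s_half.mineralizable_N *= 0.5
    for t in range(5):
        r_full = sd.mineralize(s_full, p, dt=1.0, t=float(t))
        r_half = sd.mineralize(s_half, p, dt=1.0, t=float(t))
        assert r_half == pytest.approx(0.5 * r_full, rel=1e-12)


def test_mineralization_cumulative_matches_analytic_integral():
    """With a slow rate, cumulative release approaches the closed-form
    integral of k1 (t+1)^(-q) times the initial pool."""
    p = long_profile()
    state = make_state(p, 0.25)
    pool0 = state.mineralizable_N.sum() * p.grid_dz
    k1, q = 1e-3, 0.5
    total = 0.0
    T = 40
    for t in range(T):
        total += sd.mineralize(state, p, dt=1.0, t=float(t), k1=k1, q_exp=q)
    analytic = pool0 * k1 * 2.0 * (np.sqrt(T + 1.0) - 1.0)
    assert total == pytest.approx(analytic, rel=0.05)
    # release is increasing and concave: daily increments shrink
    assert sd.mineralize(state, p, dt=1.0, t=1.0, k1=k1) > sd.mineralize(
        state, p, dt=1.0, t=30.0, k1=k1
    )
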