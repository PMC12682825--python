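"""Root architecture growth: determinism, impedance gating, the carbon
priority waterfall, branching and depth-profile accounting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stopsignal.phenotypes import Phenotype
from stopsignal.rootsys import (
    RootClassParams,
    apportion_to_nodes,
    elongate_roots,
    emit_branches,
    initialize_root_system,
    maize_default_classes,
    root_length_density,
)

ANY_NODE = lambda z: np.zeros(np.asarray(z, dtype=float).shape, dtype=int)  # noqa: E731


def toy_classes(v_axial=1.0, v_lateral=1.0, density=0.0, grav=0.0):
    """Minimal two-class card with equal per-cm carbon cost for both classes."""
    return {
        "primary": RootClassParams(
            "primary", potential_elongation=v_axial, diameter=0.1,
            branching_density=density, insertion_angle=0.0,
            gravitropism_rate=grav, branching_delay=3.0,
        ),
        "lateral": RootClassParams(
            "lateral", potential_elongation=v_lateral, diameter=0.1,
            branching_density=0.0, insertion_angle=80.0, gravitropism_rate=grav,
        ),
    }


def test_initialization_deterministic_and_seed_only_rotates():
    classes = maize_default_classes()
    s1 = initialize_root_system(classes, seed=7)
    s2 = initialize_root_system(classes, seed=7)
    s3 = initialize_root_system(classes, seed=8)
    assert np.array_equal(s1.r_tip, s2.r_tip)
    assert np.array_equal(s1.r_dir, s2.r_dir)
    # different seed: same lengths and depth, different azimuth
    assert s1.r_length == pytest.approx(s3.r_length)
    assert s1.r_tip[0, 2] == pytest.approx(s3.r_tip[0, 2])
    assert not np.allclose(s1.r_dir[0, :2], s3.r_dir[0, :2])


def test_initial_carbon_is_segment_volume_times_cost():
    classes = maize_default_classes()
    s = initialize_root_system(classes, seed=1)
    expected = s.segment_quantum * classes["primary"].cost_per_cm
    assert s.carbon_invested == pytest.approx(expected)


def test_ceiling_impedance_stops_growth_and_spends_nothing():
    s = initialize_root_system(toy_classes(), seed=0)
    tip_before = s.r_tip.copy()
    used = elongate_roots(s, np.array([5000.0]), ANY_NODE, Phenotype(1, 1), 1.0, dt=1.0)
    assert used == 0.0
    assert np.array_equal(s.r_tip, tip_before)


def test_zero_impedance_full_potential_advance():
    s = initialize_root_system(toy_classes(v_axial=2.5), seed=0)
    z0 = s.r_tip[0, 2]
    elongate_roots(s, np.array([0.0]), ANY_NODE, Phenotype(1, 1), 10.0, dt=1.0)
    assert s.r_tip[0, 2] == pytest.approx(z0 + 2.5)


def test_priority_waterfall_axial_first_laterals_scaled():
    """With equal axial and lateral demand and budget = 3/4 of the total,
    the axis is fully met and the lateral gets the remainder (half)."""
    classes = toy_classes()
    s = initialize_root_system(classes, seed=0)
    # attach one lateral with the same cost rate and potential as the axis
    lat_code = s.class_code("lateral")
    base = s.r_tip[0].copy()
    s._append_roots(lat_code, base[None, :], np.array([[1.0, 0.0, 0.0]]), [0], day=0.0)
    cost = classes["primary"].cost_per_cm
    budget = 1.5 * cost  # demand is 1 cm each -> total 2*cost
    used = elongate_roots(s, np.array([0.0]), ANY_NODE, Phenotype(1, 1), budget, dt=1.0)
    assert used == pytest.approx(budget, rel=1e-9)
    assert s.r_length[0] == pytest.approx(1.0 + 1.0)  # initial segment + full growth
    assert s.r_length[1] == pytest.approx(0.5, rel=1e-9)


def test_negative_budget_rejected():
    s = initialize_root_system(toy_classes(), seed=0)
    with pytest.raises(ValueError):
        elongate_roots(s, np.array([0.0]), ANY_NODE, Phenotype(1, 1), -1.0, dt=1.0)


def test_no_branching_without_density():
    s = initialize_root_system(toy_classes(density=0.0), seed=0)
    for day in range(1, 10):
        elongate_roots(s, np.array([0.0]), ANY_NODE, Phenotype(1, 1), 10.0, dt=1.0, day=day - 1)
        emit_branches(s, day)
    assert np.sum(s.r_class == s.class_code("lateral")) == 0


def test_lateral_spacing_two_per_cm():
    """10 cm of mature axial tissue at 2 laterals/cm yields 20 laterals."""
    s = initialize_root_system(toy_classes(density=2.0), seed=0)
    for day in range(11):
        elongate_roots(s, np.array([0.0]), ANY_NODE, Phenotype(1, 1), 10.0, dt=1.0, day=day)
        emit_branches(s, day + 1)
    # tissue older than the 3 d branching delay: axis length at day 8,
    # i.e. the 1 cm germination segment + 9 days of 1 cm growth = 10 cm
    mature = s.axis_len_by_day[0][8]
    assert mature == pytest.approx(10.0)
    n_lat = int(np.sum(s.r_class == s.class_code("lateral")))
    assert n_lat == 20


def test_nodal_whorl_emerges_on_schedule():
    classes = maize_default_classes()
    s = initialize_root_system(classes, seed=3)
    code = s.class_code("nodal_1")
    for day in range(1, 8):
        emit_branches(s, day)
    assert np.sum(s.r_class == code) == 0
    emit_branches(s, 8)
    assert np.sum(s.r_class == code) == classes["nodal_1"].count_at_emergence


def test_apportion_vertical_segment_split_across_nodes():
    out = apportion_to_nodes(
        np.array([0.0]), np.array([10.0]), np.array([10.0]), n_nodes=10, dz=2.0
    )
    assert out[:5] == pytest.approx(np.full(5, 2.0))
    assert out[5:].sum() == 0


def test_apportion_horizontal_segment_single_node():
    out = apportion_to_nodes(
        np.array([7.0]), np.array([7.0]), np.array([4.0]), n_nodes=10, dz=2.0
    )
    assert out[3] == pytest.approx(4.0)
    assert out.sum() == pytest.approx(4.0)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_apportion_conserves_total_length(seed):
    rng = np.random.default_rng(seed)
    k = rng.integers(1, 50)
    z0 = rng.uniform(0, 98, k)
    z1 = z0 + rng.uniform(0, 3, k)
    # segment length >= z-extent (slanted segments)
    length = (z1 - z0) * (1.0 + rng.uniform(0, 2, k))
    out = apportion_to_nodes(z0, z1, length, n_nodes=51, dz=2.0)
    assert out.sum() == pytest.approx(length.sum(), rel=1e-9)


def test_grown_system_rld_matches_total_length():
    s = initialize_root_system(maize_default_classes(), seed=11, domain_depth=130.0)
    for day in range(15):
        elongate_roots(s, np.array([500.0]), ANY_NODE, Phenotype(1, 1), 0.05, dt=1.0, day=day)
        emit_branches(s, day + 1)
    rld = root_length_density(s, n_nodes=65, dz=2.0)
    assert rld.sum() == pytest.approx(s.total_length, rel=1e-9)
    assert s.total_length > 10.0


def test_carbon_accounting_closes_during_growth():
    s = initialize_root_system(maize_default_classes(), seed=5)
    c0 = s.carbon_construction
    spent = 0.0
    for day in range(10):
        spent += elongate_roots(
            s, np.array([800.0]), ANY_NODE, Phenotype(1, 0.5), 0.02, dt=1.0, day=day
        )
        emit_branches(s, day + 1)
    assert s.carbon_construction - c0 == pytest.approx(spent, rel=1e-9)
    _, cost, _ = s.class_param_arrays()
    # total construction equals sum of per-class length x cost (incl. seed segment)
    by_class = sum(
        s.length_by_class[name] * s.classes[name].cost_per_cm for name in s.class_names
    )
    assert s.carbon_construction == pytest.approx(by_class, rel=1e-9)


def test_max_depth_nondecreasing_in_axial_ability_under_hard_soil():
    depths = []
    for a_ax in (0.3, 1.0, 2.0):
        s = initialize_root_system(maize_default_classes(), seed=2, domain_depth=130.0)
        pr = np.full(65, 3000.0)
        for day in range(20):
            elongate_roots(
                s, pr, lambda z: np.clip((np.asarray(z) / 2).astype(int), 0, 64),
                Phenotype(a_ax, 1.0), 1.0, dt=1.0, day=day,
            )
            emit_branches(s, day + 1)
        depths.append(s.max_tip_depth())
    assert depths[0] <= depths[1] <= depths[2]
    assert depths[0] < depths[2]


def test_plastic_laterals_avoid_hard_topsoil():
    """Lateral length in a hard-dry topsoil is smaller for a sensitive
    lateral stop signal (a_lateral = 0.2) than an insensitive one (2.0)."""
    def grow(a_lat):
        s = initialize_root_system(maize_default_classes(), seed=9, domain_depth=130.0)
        pr = np.where(np.arange(65) * 2.0 < 30.0, 3500.0, 800.0)
        nod = lambda z: np.clip((np.asarray(z) / 2).astype(int), 0, 64)  # noqa: E731
        for day in range(25):
            elongate_roots(s, pr, nod, Phenotype(2.0, a_lat), 1.0, dt=1.0, day=day)
            emit_branches(s, day + 1)
        bz, tz, ln, cc = s.segments_z()
        lat = cc == s.class_code("lateral")
        top = 0.5 * (bz + tz) <= 30.0
        return ln[lat & top].sum()

    assert grow(0.2) < grow(2.0)
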