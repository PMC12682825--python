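"""Pedotransfer functions, retention curves, penetration resistance and the
native-to-cultivated profile transformation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stopsignal import soils
from stopsignal.soils import (
    H_FIELD_CAPACITY,
    H_WILTING_POINT,
    HydraulicParams,
    SoilDomainError,
    SoilLayer,
    build_profile,
    conductivity_K,
    cultivate,
    derive_hydraulics,
    fit_van_genuchten,
    pedotransfer_saxton_rawls,
    penetration_resistance,
    retention_theta,
    sandy_loam_profile,
    silt_loam_profile,
)

# Frozen values from an independent transcription of the published
# Saxton-Rawls (2006) regression equations (straight-line calculator script).
SR_ORACLE = [
    # (sand, clay, OM, Db) -> (theta_fc, theta_pwp, theta_s)
    ((0.60, 0.10, 2.0, None), (0.183414, 0.076649, 0.437756)),
    ((0.20, 0.45, 1.0, None), (0.403800, 0.267987, 0.488237)),
    ((0.65, 0.10, 2.0, 1.45), (0.175286, 0.076239, 0.452830)),
]


@pytest.mark.parametrize("args,expected", SR_ORACLE)
def test_saxton_rawls_matches_independent_oracle(args, expected):
    fc, pwp, ts, _ = pedotransfer_saxton_rawls(*args)
    assert fc == pytest.approx(expected[0], abs=1e-6)
    assert pwp == pytest.approx(expected[1], abs=1e-6)
    assert ts == pytest.approx(expected[2], abs=1e-6)


def test_clay_raises_wilting_point():
    _, pwp_sandy, _, _ = pedotransfer_saxton_rawls(0.60, 0.10, 2.0)
    _, pwp_clayey, _, _ = pedotransfer_saxton_rawls(0.20, 0.45, 1.0)
    assert pwp_clayey > pwp_sandy


@pytest.mark.parametrize(
    "sand,clay,om",
    [(-0.1, 0.2, 1.0), (0.2, 1.2, 1.0), (0.8, 0.5, 1.0), (0.3, 0.3, 12.0)],
)
def test_pedotransfer_domain_errors(sand, clay, om):
    with pytest.raises(SoilDomainError):
        pedotransfer_saxton_rawls(sand, clay, om)


@pytest.mark.parametrize("texture", sorted(soils.TEXTURE_CENTROIDS))
def test_van_genuchten_fit_hits_both_anchors(texture):
    layer = SoilLayer(0.0, 10.0, texture, bulk_density=1.45, organic_matter=1.0)
    p = derive_hydraulics(layer)
    assert p.n_shape > 1.0
    assert retention_theta(H_FIELD_CAPACITY, p) == pytest.approx(p.theta_fc, abs=1e-6)
    assert retention_theta(H_WILTING_POINT, p) == pytest.approx(p.theta_pwp, abs=1e-6)


def test_fit_rejects_inverted_anchors():
    with pytest.raises(SoilDomainError):
        fit_van_genuchten(0.05, 0.45, 0.10, 0.30)  # fc < pwp


def test_retention_limits_and_monotonicity(sandy_hydraulics):
    p = sandy_hydraulics
    assert retention_theta(0.0, p) == pytest.approx(p.theta_s)
    # dry-limit approach to theta_r (rate depends on the fitted n)
    assert retention_theta(-1.0e7, p) == pytest.approx(p.theta_r, abs=1e-2)
    assert retention_theta(-1.0e10, p) < retention_theta(-1.0e7, p)
    h = -np.logspace(-2, 7, 300)[::-1]  # increasing toward zero
    theta = retention_theta(h, p)
    assert np.all(np.diff(theta) >= -1e-15)
    K = conductivity_K(h, p)
    assert np.all(np.diff(K) >= -1e-15)
    assert conductivity_K(0.0, p) == pytest.approx(p.K_s)


def test_retention_against_closed_form(sandy_hydraulics):
    # independent evaluation of the van Genuchten formula at a midpoint
    p = sandy_hydraulics
    h = -1000.0
    m = 1.0 - 1.0 / p.n_shape
    expected = p.theta_r + (p.theta_s - p.theta_r) / (
        1.0 + abs(p.alpha * h) ** p.n_shape
    ) ** m
    assert retention_theta(h, p) == pytest.approx(expected, rel=1e-12)


def test_penetration_resistance_spot_value(sandy_hydraulics):
    """Closed form log10(PR) = 0.35 log10(|psi| S) + 0.93 Db + 1.26 at
    psi = -100 kPa, S = 0.5, Db = 1.4 gives 1434.3 kPa (script oracle)."""
    p = sandy_hydraulics
    h = -100.0 * soils.CM_PER_KPA
    theta = retention_theta(h, p)
    sat = theta / p.theta_s
    pr = penetration_resistance(theta, p, 1.4, coeffs=(0.35, 0.93, 1.26))
    expected = 10.0 ** (0.35 * np.log10(100.0 * sat) + 0.93 * 1.4 + 1.26)
    assert pr == pytest.approx(expected, rel=1e-9)
    # the frozen spot value at S = 0.5 exactly
    assert 10.0 ** (0.35 * np.log10(100.0 * 0.5) + 0.93 * 1.4 + 1.26) == pytest.approx(
        1434.2984, abs=1e-3
    )


def test_penetration_resistance_monotonicities(sandy_hydraulics):
    """Decreasing in theta, increasing in Db, non-decreasing in depth on a
    random grid of 1000 evaluations."""
    p = sandy_hydraulics
    rng = np.random.default_rng(42)
    theta = np.sort(rng.uniform(p.theta_r + 1e-6, p.theta_s - 1e-6, 1000))
    pr = penetration_resistance(theta, p, 1.4)
    assert np.all(np.diff(pr) < 0)

    db = np.sort(rng.uniform(1.0, 1.8, 1000))
    pr_db = penetration_resistance(0.2, p, db)
    assert np.all(np.diff(pr_db) > 0)

    depth = np.sort(rng.uniform(0, 100, 1000))
    pr_z = penetration_resistance(0.2, p, 1.4, depth=depth, depth_gradient=2.0)
    assert np.all(np.diff(pr_z) >= 0)


def test_penetration_resistance_wet_dry_and_compaction(sandy_hydraulics):
    p = sandy_hydraulics
    assert penetration_resistance(p.theta_fc, p, 1.4) < penetration_resistance(
        p.theta_pwp, p, 1.4
    )
    # 10 % densification (native -> cultivated) raises PR at equal theta
    assert penetration_resistance(0.2, p, 1.4 * 1.10) > penetration_resistance(
        0.2, p, 1.4
    )
    with pytest.raises(SoilDomainError):
        penetration_resistance(p.theta_s + 0.05, p, 1.4)


def test_cultivate_transforms_only_the_a_horizon():
    native = sandy_loam_profile()
    cult = cultivate(native)
    a0, a1 = native.layers[0], cult.layers[0]
    assert a1.thickness == pytest.approx(a0.thickness / 2)
    assert a1.organic_matter == pytest.approx(a0.organic_matter / 2)
    assert a1.bulk_density == pytest.approx(a0.bulk_density * 1.10)
    # deeper layers keep their properties, shifted upward to the surface
    shift = a0.thickness - a1.thickness
    for ly_n, ly_c in zip(native.layers[1:], cult.layers[1:]):
        assert ly_c.top_depth == pytest.approx(ly_n.top_depth - shift)
        assert ly_c.bottom_depth == pytest.approx(ly_n.bottom_depth - shift)
        assert ly_c.bulk_density == ly_n.bulk_density
        assert ly_c.organic_matter == ly_n.organic_matter
        assert ly_c.hydraulics == ly_n.hydraulics
    assert cult.layers[0].top_depth == 0.0


def test_cultivate_example_40cm_horizon():
    prof = build_profile(
        [
            SoilLayer(0.0, 40.0, "silt loam", bulk_density=1.30, organic_matter=2.0),
            SoilLayer(40.0, 80.0, "silty clay", bulk_density=1.45, organic_matter=0.5),
        ]
    )
    cult = cultivate(prof)
    assert cult.layers[0].bottom_depth == pytest.approx(20.0)
    assert cult.layers[0].organic_matter == pytest.approx(1.0)
    assert cult.layers[0].bulk_density == pytest.approx(1.43)


@pytest.mark.parametrize("factory,n_layers,depth", [
    (sandy_loam_profile, 3, 130.0),
    (silt_loam_profile, 3, 160.0),
])
def test_builtin_profiles(factory, n_layers, depth):
    prof = factory()
    assert len(prof.layers) == n_layers
    assert prof.total_depth == depth
    # every node maps to the layer containing its center
    for i, z in enumerate(prof.node_depths):
        ly = prof.layers[prof.layer_index[i]]
        assert ly.top_depth - 1e-9 <= z <= ly.bottom_depth + 1e-9
    # porosity within a plausible range for these alluvial horizons
    assert np.all(prof.theta_s >= 0.38)
    assert np.all(prof.theta_s <= 0.52)


def test_profile_requires_contiguous_layers():
    with pytest.raises(SoilDomainError):
        build_profile(
            [
                SoilLayer(0.0, 30.0, "silt loam", 1.3, 2.0),
                SoilLayer(40.0, 80.0, "silty clay", 1.4, 0.5),
            ]
        )


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    sand=st.floats(0.05, 0.85),
    clay=st.floats(0.05, 0.55),
    om=st.floats(0.0, 6.0),
)
def test_pedotransfer_ordering_property(sand, clay, om):
    """theta_pwp < theta_fc < theta_s for any admissible texture."""
    if sand + clay > 0.95:
        return
    fc, pwp, ts, ks = pedotransfer_saxton_rawls(sand, clay, om)
    assert pwp < fc < ts
    assert ks > 0
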