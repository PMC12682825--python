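"""Discretized maize root system growing under mechanical impedance.

The architecture is a collection of root axes (primary, seminal, nodal
whorls) carrying first-order laterals.  Geometry is fully 3-D (z positive
downward) but the soil is laterally homogeneous, so only tip depth couples
to soil state.  Each day every active tip elongates by

    potential_elongation * y(PR at tip) * dt

where y is the stop-signal growth-reduction factor with the class-specific
exponent (a_axial for axes, a_lateral for laterals), subject to the carbon
budget: axes are satisfied before laterals, and a lateral shortfall scales
all lateral growth proportionally.  Grown length is cut into ~1 cm segments
for bookkeeping, RSML export and depth-profile coupling.

State lives in flat numpy arrays (one row per root axis, per-day segment
blocks) so a 40-day system with thousands of laterals advances in
vectorized steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phenotypes import GROWTH_CEILING_KPA, Phenotype

__all__ = [
    "RootClassParams",
    "RootSystem",
    "maize_default_classes",
    "initialize_root_system",
    "elongate_roots",
    "emit_branches",
    "root_length_density",
    "apportion_to_nodes",
]

LATERAL = "lateral"
AXIAL_CLASSES = ("primary", "seminal", "nodal_1", "nodal_2", "nodal_3", "nodal_4")


@dataclass(frozen=True)
class RootClassParams:
    """Per-class growth parameters (lengths cm, times d, carbon g C)."""

    class_id: str
    potential_elongation: float  # cm d-1
    diameter: float  # cm
    branching_density: float = 0.0  # laterals per cm, axial classes only
    emergence_day: float = 0.0
    count_at_emergence: int = 1
    insertion_angle: float = 0.0  # degrees from vertical (axes) / from parent (laterals)
    gravitropism_rate: float = 0.0  # degrees per day toward vertical
    specific_root_cost: float = 0.02  # g C per cm3 tissue
    branching_delay: float = 3.0  # d of tissue age before laterals emerge

    def __post_init__(self) -> None:
        if self.potential_elongation <= 0 or self.diameter <= 0:
            raise ValueError(f"bad growth parameters for class {self.class_id}")
        if self.branching_density < 0:
            raise ValueError("branching_density must be >= 0")
        if self.class_id == LATERAL and self.branching_density != 0:
            raise ValueError("lateral class cannot branch")

    @property
    def cross_section(self) -> float:
        return np.pi * (self.diameter / 2.0) ** 2

    @property
    def cost_per_cm(self) -> float:
        return self.cross_section * self.specific_root_cost


def maize_default_classes(
    axial_elongation: float = 2.5,
    lateral_elongation: float = 0.8,
    branching_density: float = 2.0,
    tissue_density: float = 0.12,
    carbon_fraction: float = 0.4,
) -> dict[str, RootClassParams]:
    """Typical maize seedling parameter card: 1 primary + 3 seminals, four
    nodal whorls (days 8/12/16/20 with 4/6/8/10 roots), 2 laterals per cm."""
    cost = tissue_density * carbon_fraction
    common = dict(
        potential_elongation=axial_elongation,
        diameter=0.1,
        branching_density=branching_density,
        specific_root_cost=cost,
    )
    return {
        "primary": RootClassParams(
            "primary", emergence_day=0, count_at_emergence=1,
            insertion_angle=5.0, gravitropism_rate=20.0, **common),
        "seminal": RootClassParams(
            "seminal", emergence_day=1, count_at_emergence=3,
            insertion_angle=35.0, gravitropism_rate=6.0, **common),
        "nodal_1": RootClassParams(
            "nodal_1", emergence_day=8, count_at_emergence=4,
            insertion_angle=45.0, gravitropism_rate=5.0, **common),
        "nodal_2": RootClassParams(
            "nodal_2", emergence_day=12, count_at_emergence=6,
            insertion_angle=50.0, gravitropism_rate=5.0, **common),
        "nodal_3": RootClassParams(
            "nodal_3", emergence_day=16, count_at_emergence=8,
            insertion_angle=55.0, gravitropism_rate=4.0, **common),
        "nodal_4": RootClassParams(
            "nodal_4", emergence_day=20, count_at_emergence=10,
            insertion_angle=60.0, gravitropism_rate=4.0, **common),
        LATERAL: RootClassParams(
            LATERAL, potential_elongation=lateral_elongation, diameter=0.03,
            branching_density=0.0, insertion_angle=75.0, gravitropism_rate=2.0,
            specific_root_cost=cost),
    }


@dataclass
class RootSystem:
    """Growing root architecture with carbon accounting.

    Root axes live in parallel arrays; segments accumulate in per-day
    blocks.  ``carbon_invested`` = construction + maintenance carbon.
    """

    classes: dict[str, RootClassParams]
    class_names: list[str]
    rng: np.random.Generator
    rng_seed: int
    segment_quantum: float = 1.0
    seed_depth: float = 2.0
    domain_depth: float = 130.0

    # per-root arrays
    r_class: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    r_tip: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    r_dir: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    r_length: np.ndarray = field(default_factory=lambda: np.empty(0))
    r_parent: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    r_emerged: np.ndarray = field(default_factory=lambda: np.empty(0))

    # per-axial-root polyline history for lateral placement
    axis_points: dict[int, list[np.ndarray]] = field(default_factory=dict)
    axis_cumlen: dict[int, list[float]] = field(default_factory=dict)
    axis_len_by_day: dict[int, dict[int, float]] = field(default_factory=dict)
    n_laterals_emitted: dict[int, int] = field(default_factory=dict)
    emitted_whorls: set = field(default_factory=set)

    # segment blocks (appended per growth step)
    seg_blocks: list[dict] = field(default_factory=list)

    carbon_construction: float = 0.0
    carbon_maintenance: float = 0.0
    length_by_class: dict[str, float] = field(default_factory=dict)

    @property
    def carbon_invested(self) -> float:
        return self.carbon_construction + self.carbon_maintenance

    @property
    def n_roots(self) -> int:
        return self.r_class.size

    @property
    def total_length(self) -> float:
        return float(self.r_length.sum())

    def class_code(self, name: str) -> int:
        return self.class_names.index(name)

    def class_param_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(elongation, cost_per_cm, circumference) indexed by class code."""
        v = np.array([self.classes[c].potential_elongation for c in self.class_names])
        cost = np.array([self.classes[c].cost_per_cm for c in self.class_names])
        circ = np.array([np.pi * self.classes[c].diameter for c in self.class_names])
        return v, cost, circ

    def is_axial(self) -> np.ndarray:
        return self.r_class != self.class_code(LATERAL)

    def max_tip_depth(self) -> float:
        return float(self.r_tip[:, 2].max()) if self.n_roots else 0.0

    # -- segment views ----------------------------------------------------

    def segments_z(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(base_z, tip_z, length, class_code) over all segments."""
        if not self.seg_blocks:
            z = np.empty(0)
            return z, z, z, np.empty(0, dtype=int)
        bz = np.concatenate([b["base"][:, 2] for b in self.seg_blocks])
        tz = np.concatenate([b["tip"][:, 2] for b in self.seg_blocks])
        ln = np.concatenate([b["length"] for b in self.seg_blocks])
        cc = np.concatenate([b["class_code"] for b in self.seg_blocks])
        return bz, tz, ln, cc

    def _append_roots(self, class_code, tips, dirs, parents, day) -> np.ndarray:
        k = len(tips)
        first = self.n_roots
        self.r_class = np.concatenate([self.r_class, np.full(k, class_code, dtype=int)])
        self.r_tip = np.vstack([self.r_tip, tips])
        self.r_dir = np.vstack([self.r_dir, dirs])
        self.r_length = np.concatenate([self.r_length, np.zeros(k)])
        self.r_parent = np.concatenate([self.r_parent, np.asarray(parents, dtype=int)])
        self.r_emerged = np.concatenate([self.r_emerged, np.full(k, float(day))])
        return np.arange(first, first + k)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    n = np.where(n < 1e-12, 1.0, n)
    return v / n


def _direction_from_vertical(angle_deg: float, azimuth: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    return np.array([np.sin(a) * np.cos(azimuth), np.sin(a) * np.sin(azimuth), np.cos(a)])


def initialize_root_system(
    class_params: dict[str, RootClassParams],
    seed: int,
    domain_depth: float = 130.0,
    segment_quantum: float = 1.0,
    seed_depth: float = 2.0,
) -> RootSystem:
    """Germination state: one primary axis of one segment below the seed.

    The primary points down with its insertion angle and a seeded random
    azimuth (the azimuth is the only stochastic element, so different seeds
    give rotated but metrically identical systems).
    """
    if "primary" not in class_params:
        raise ValueError("class parameters must include 'primary'")
    if LATERAL not in class_params:
        raise ValueError("class parameters must include 'lateral'")
    names = sorted(class_params)
    system = RootSystem(
        classes=class_params,
        class_names=names,
        rng=np.random.default_rng(seed),
        rng_seed=seed,
        segment_quantum=segment_quantum,
        seed_depth=seed_depth,
        domain_depth=domain_depth,
    )
    p = class_params["primary"]
    azim = system.rng.uniform(0, 2 * np.pi)
    d = _direction_from_vertical(p.insertion_angle, azim)
    base = np.array([0.0, 0.0, seed_depth])
    length = segment_quantum
    tip = base + length * d
    code = system.class_code("primary")
    ids = system._append_roots(code, tip[None, :], d[None, :], [-1], day=0.0)
    system.r_length[ids] = length
    system.seg_blocks.append(
        dict(
            base=base[None, :], tip=tip[None, :], length=np.array([length]),
            class_code=np.array([code]), root_id=ids.copy(), day=np.zeros(1),
        )
    )
    system.carbon_construction += length * p.cost_per_cm
    system.length_by_class = {name: 0.0 for name in names}
    system.length_by_class["primary"] = length
    rid = int(ids[0])
    system.axis_points[rid] = [base.copy(), tip.copy()]
    system.axis_cumlen[rid] = [0.0, length]
    system.axis_len_by_day[rid] = {0: length}
    system.n_laterals_emitted[rid] = 0
    system.emitted_whorls.add("primary")
    return system


def _emit_axes(system: RootSystem, name: str, day: int) -> None:
    p = system.classes[name]
    code = system.class_code(name)
    k = p.count_at_emergence
    base_azim = system.rng.uniform(0, 2 * np.pi)
    azims = base_azim + 2 * np.pi * np.arange(k) / k
    dirs = np.stack([_direction_from_vertical(p.insertion_angle, a) for a in azims])
    base = np.array([0.0, 0.0, system.seed_depth])
    tips = np.repeat(base[None, :], k, axis=0)
    ids = system._append_roots(code, tips, dirs, [-1] * k, day=float(day))
    for rid in ids:
        rid = int(rid)
        system.axis_points[rid] = [base.copy()]
        system.axis_cumlen[rid] = [0.0]
        system.axis_len_by_day[rid] = {day: 0.0}
        system.n_laterals_emitted[rid] = 0


def _axis_point_and_dir(system: RootSystem, rid: int, s: float) -> tuple[np.ndarray, np.ndarray]:
    """Position and local direction at arc length s along axis rid."""
    cum = system.axis_cumlen[rid]
    pts = system.axis_points[rid]
    cum_arr = np.asarray(cum)
    s = min(max(s, 0.0), cum_arr[-1])
    j = int(np.searchsorted(cum_arr, s, side="right")) - 1
    j = min(max(j, 0), len(pts) - 2)
    seg_len = cum_arr[j + 1] - cum_arr[j]
    frac = 0.0 if seg_len <= 1e-12 else (s - cum_arr[j]) / seg_len
    pos = pts[j] + frac * (pts[j + 1] - pts[j])
    d = _unit(pts[j + 1] - pts[j])
    return pos, d


def emit_branches(system: RootSystem, day: int) -> int:
    """Emit nodal/seminal whorls due today and new laterals on mature tissue.

    Laterals appear at fixed spacing 1/branching_density along axial tissue
    older than the branching delay; a whorl class emits count_at_emergence
    axes on its emergence day.  Returns the number of new roots.
    """
    new_roots = 0
    # 1. whorls
    for name in system.class_names:
        if name == LATERAL or name in system.emitted_whorls:
            continue
        if system.classes[name].emergence_day <= day:
            before = system.n_roots
            _emit_axes(system, name, day)
            system.emitted_whorls.add(name)
            new_roots += system.n_roots - before

    # 2. laterals on mature axial tissue
    lat = system.classes[LATERAL]
    lat_code = system.class_code(LATERAL)
    for rid, emitted in list(system.n_laterals_emitted.items()):
        cls = system.classes[system.class_names[system.r_class[rid]]]
        if cls.branching_density <= 0:
            continue
        mature_day = int(day - cls.branching_delay)
        branchable = system.axis_len_by_day[rid].get(mature_day)
        if branchable is None:
            if mature_day < min(system.axis_len_by_day[rid]):
                continue
            branchable = max(
                v for d, v in system.axis_len_by_day[rid].items() if d <= mature_day
            )
        spacing = 1.0 / cls.branching_density
        n_total = int(np.floor(branchable / spacing))
        n_new = n_total - emitted
        if n_new <= 0:
            continue
        bases, dirs = [], []
        for k in range(emitted, n_total):
            s = (k + 0.5) * spacing
            pos, axis_dir = _axis_point_and_dir(system, rid, s)
            phi = system.rng.uniform(0, 2 * np.pi)
            # orthonormal frame around the local axis direction
            ref = np.array([1.0, 0.0, 0.0])
            if abs(axis_dir[0]) > 0.9:
                ref = np.array([0.0, 1.0, 0.0])
            e1 = _unit(np.cross(axis_dir, ref))
            e2 = np.cross(axis_dir, e1)
            beta = np.deg2rad(lat.insertion_angle)
            d = np.cos(beta) * axis_dir + np.sin(beta) * (np.cos(phi) * e1 + np.sin(phi) * e2)
            d = _unit(d)
            if d[2] < 0 and pos[2] < 2.0:
                d[2] = abs(d[2])  # keep shallow laterals from exiting the surface
                d = _unit(d)
            bases.append(pos)
            dirs.append(d)
        system._append_roots(
            lat_code, np.asarray(bases), np.asarray(dirs), [rid] * n_new, day=float(day)
        )
        system.n_laterals_emitted[rid] = n_total
        new_roots += n_new
    return new_roots


def _gravitropism(system: RootSystem, dt: float) -> None:
    rates = np.array(
        [system.classes[c].gravitropism_rate for c in system.class_names]
    )[system.r_class]
    d = system.r_dir
    cosang = np.clip(d[:, 2], -1.0, 1.0)
    ang = np.arccos(cosang)
    dphi = np.minimum(np.deg2rad(rates * dt), ang)
    horiz = d.copy()
    horiz[:, 2] = 0.0
    hnorm = np.linalg.norm(horiz, axis=1)
    ok = (hnorm > 1e-12) & (dphi > 0)
    new_ang = ang[ok] - dphi[ok]
    hhat = horiz[ok] / hnorm[ok, None]
    nd = np.cos(new_ang)[:, None] * np.array([0.0, 0.0, 1.0]) + np.sin(new_ang)[:, None] * hhat
    system.r_dir[ok] = nd


def growth_potential(
    system: RootSystem, pr_nodes: np.ndarray, node_of_depth, phenotype: Phenotype, dt: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-root potential elongation (cm), its carbon cost, and axial mask."""
    v, cost, _ = system.class_param_arrays()
    tipz = np.clip(system.r_tip[:, 2], 0.0, system.domain_depth - 1e-6)
    pr = pr_nodes[node_of_depth(tipz)]
    axial = system.is_axial()
    a = np.where(axial, phenotype.a_axial, phenotype.a_lateral)
    ratio = np.minimum(pr / GROWTH_CEILING_KPA, 1.0)
    y = np.clip(1.0 - ratio ** a, 0.0, 1.0)
    dl_pot = v[system.r_class] * y * dt
    return dl_pot, dl_pot * cost[system.r_class], axial


def elongate_roots(
    system: RootSystem,
    pr_nodes: np.ndarray,
    node_of_depth,
    phenotype: Phenotype,
    carbon_budget_root: float,
    dt: float,
    day: int = 0,
) -> float:
    """Advance every tip by impedance-limited growth within the carbon budget.

    Axial classes are satisfied first; any shortfall scales lateral growth
    proportionally.  Returns construction carbon used (<= budget).
    """
    if carbon_budget_root < 0:
        raise ValueError("carbon budget must be >= 0")
    if system.n_roots == 0:
        return 0.0

    dl_pot, demand, axial = growth_potential(system, pr_nodes, node_of_depth, phenotype, dt)
    ax_demand = float(demand[axial].sum())
    lat_demand = float(demand[~axial].sum())

    safety = 1.0 - 1e-12
    if carbon_budget_root * safety >= ax_demand:
        f_ax = 1.0
        rem = carbon_budget_root * safety - ax_demand
        f_lat = 1.0 if lat_demand <= rem else (rem / lat_demand if lat_demand > 0 else 0.0)
    else:
        f_ax = carbon_budget_root * safety / ax_demand if ax_demand > 0 else 0.0
        f_lat = 0.0

    dl = np.where(axial, dl_pot * f_ax, dl_pot * f_lat)

    _gravitropism(system, dt)

    # boundary deflection before advancing
    d = system.r_dir
    tip = system.r_tip
    hitting_bottom = tip[:, 2] + dl * d[:, 2] > system.domain_depth - 0.1
    if hitting_bottom.any():
        d[hitting_bottom, 2] = 0.0
        d[hitting_bottom] = _unit(d[hitting_bottom])
    hitting_top = tip[:, 2] + dl * d[:, 2] < 0.1
    if hitting_top.any():
        d[hitting_top, 2] = np.abs(d[hitting_top, 2])
        d[hitting_top] = _unit(d[hitting_top])

    grown = dl > 1e-9
    carbon_used = 0.0
    if grown.any():
        idx = np.flatnonzero(grown)
        q = system.segment_quantum
        dli = dl[idx]
        reps = np.maximum(np.ceil(dli / q - 1e-12).astype(int), 1)
        root_rep = np.repeat(idx, reps)
        w = np.arange(reps.sum()) - np.repeat(np.cumsum(reps) - reps, reps)
        s = w * q
        e = np.minimum(s + q, np.repeat(dli, reps))
        base = tip[root_rep] + s[:, None] * d[root_rep]
        segtip = tip[root_rep] + e[:, None] * d[root_rep]
        seg_len = e - s
        _, cost, _ = system.class_param_arrays()
        system.seg_blocks.append(
            dict(
                base=base, tip=segtip, length=seg_len,
                class_code=system.r_class[root_rep], root_id=root_rep.copy(),
                day=np.full(seg_len.size, float(day)),
            )
        )
        carbon_used = float((dl * cost[system.r_class]).sum())
        system.carbon_construction += carbon_used
        system.r_tip = tip + dl[:, None] * d
        system.r_length = system.r_length + dl
        for name in system.class_names:
            code = system.class_code(name)
            mask = system.r_class == code
            add = float(dl[mask].sum())
            if add:
                system.length_by_class[name] = system.length_by_class.get(name, 0.0) + add

    # record axial polylines / daily lengths for branching
    for rid in system.axis_points:
        if dl[rid] > 1e-9:
            system.axis_points[rid].append(system.r_tip[rid].copy())
            system.axis_cumlen[rid].append(system.axis_cumlen[rid][-1] + float(dl[rid]))
        system.axis_len_by_day[rid][day] = system.axis_cumlen[rid][-1]

    return carbon_used


def apportion_to_nodes(
    base_z: np.ndarray, tip_z: np.ndarray, lengths: np.ndarray, n_nodes: int, dz: float
) -> np.ndarray:
    """Distribute segment lengths over depth bins by z-extent overlap."""
    out = np.zeros(n_nodes)
    if lengths.size == 0:
        return out
    z0 = np.minimum(base_z, tip_z)
    z1 = np.maximum(base_z, tip_z)
    if np.any(z0 < -1e-6):
        raise ValueError("segment above the soil surface")
    span = z1 - z0
    flat = span <= 1e-12
    if flat.any():
        bins = np.clip((z0[flat] / dz).astype(int), 0, n_nodes - 1)
        np.add.at(out, bins, lengths[flat])
    sl = ~flat
    if sl.any():
        z0s, z1s, Ls = z0[sl], z1[sl], lengths[sl]
        spans = z1s - z0s
        b0 = np.floor(z0s / dz).astype(int)
        kmax = int(np.max(np.floor(z1s / dz).astype(int) - b0)) + 1
        for k in range(kmax):
            b = b0 + k
            lo = b * dz
            ov = np.clip(np.minimum(z1s, lo + dz) - np.maximum(z0s, lo), 0.0, None)
            contrib = Ls * ov / spans
            np.add.at(out, np.clip(b, 0, n_nodes - 1), contrib)
    return out


def root_length_density(system: RootSystem, n_nodes: int, dz: float) -> np.ndarray:
    """Root length (cm) per soil node over all segments."""
    bz, tz, ln, _ = system.segments_z()
    return apportion_to_nodes(bz, tz, ln, n_nodes, dz)


def root_surface_density(system: RootSystem, n_nodes: int, dz: float) -> np.ndarray:
    """Root surface area (cm2) per soil node (cylindrical segments)."""
    bz, tz, ln, cc = system.segments_z()
    _, _, circ = system.class_param_arrays()
    return apportion_to_nodes(bz, tz, ln * circ[cc], n_nodes, dz)
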