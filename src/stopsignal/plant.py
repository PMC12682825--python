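"""Daily plant carbon economy, resource demand and stress indices.

Carbon supply combines seed-reserve draw (first days after germination)
with a light-use-efficiency shoot source modulated by atmospheric CO2 and
by the more limiting of water and N stress.  Allocation follows a strict
priority waterfall: maintenance respiration first, then shoot growth, then
axial root growth, then lateral root growth; unallocated carbon carries to
a reserve.

Stress is the published index 1 - (u - m)/(o - m) on cumulative resource
uptake u relative to optimal (o) and minimal (m) plant contents, clamped to
[0, 1]: 0 means no stress, 1 severe stress.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PlantParams",
    "PlantState",
    "CarbonBudget",
    "carbon_supply",
    "co2_factor",
    "allocate",
    "stress_index",
    "n_uptake",
    "grow_shoot",
]

#: micromol N per gram N
UMOL_PER_G_N = 1.0e6 / 14.0


@dataclass(frozen=True)
class PlantParams:
    """Shoot and resource-economy constants (defaults: maize seedling).

    The light source is a light-use-efficiency model: supply =
    LUE * PAR * ground_area * f_int(LAI) * f_CO2 * (1 - max stress), with
    f_CO2 a saturating response normalized to 1 at 270 ppm.
    """

    lue: float = 3.0  # g C per MJ intercepted PAR
    par: float = 4.0e-4  # MJ cm-2 d-1 incident
    ground_area: float = 400.0  # cm2 per plant (1-D column cross-section)
    k_light: float = 0.6  # canopy extinction coefficient
    co2_half_sat: float = 200.0  # ppm
    co2_reference: float = 270.0  # ppm at which f_CO2 = 1
    seed_reserve: float = 0.25  # g C
    seed_release_days: float = 10.0
    sla: float = 200.0  # cm2 leaf per g leaf DW
    leaf_mass_fraction: float = 0.6
    shoot_c_fraction: float = 0.45  # g C per g shoot DW
    shoot_rgr: float = 0.25  # d-1 potential relative growth rate (young plant)
    shoot_supply_fraction: float = 0.65  # sink-capacity cap on the shoot share
    maintenance_shoot: float = 0.01  # g C per g shoot C per d
    maintenance_root: float = 0.025  # g C per g root C per d (fine-root respiration)
    transpiration_per_leaf: float = 0.30  # cm3 water per cm2 leaf per d
    water_minimal_fraction: float = 0.3  # m = fraction of o for water
    n_optimal_pct: float = 4.0  # % of shoot DW as N for zero N stress
    n_minimal_pct: float = 1.0
    i_max: float = 2.5  # umol N per cm2 root surface per d
    k_m: float = 1.0  # umol cm-3 Michaelis constant (low-affinity range)
    stress_impact: float = 0.7  # fraction of the source lost at severe stress
    max_uptake_per_cm: float = 0.4  # cm3 water per cm root per d in wet soil
    stress_window: int = 3  # moving-average days for growth feedback
    initial_shoot_dw: float = 0.05  # g
    initial_plant_n: float = 500.0  # umol (seed N)


@dataclass
class PlantState:
    """Shoot state plus cumulative resource bookkeeping."""

    shoot_biomass: float  # g DW
    leaf_area: float  # cm2
    seed_reserve: float  # g C remaining
    reserve: float = 0.0  # g C carried over from unallocated supply
    plant_N: float = 0.0  # umol, cumulative uptake + seed N
    cum_water_uptake: float = 0.0  # cm3
    cum_potential_transpiration: float = 0.0  # cm3
    cum_n_uptake: float = 0.0  # umol
    water_stress: float = 0.0
    n_stress: float = 0.0
    water_stress_history: list = field(default_factory=list)
    n_stress_history: list = field(default_factory=list)

    def smoothed_stresses(self, window: int) -> tuple[float, float]:
        if not self.water_stress_history:
            return 0.0, 0.0
        w = self.water_stress_history[-window:]
        n = self.n_stress_history[-window:]
        return float(np.mean(w)), float(np.mean(n))


@dataclass(frozen=True)
class CarbonBudget:
    """Result of one day's allocation waterfall (all g C d-1)."""

    supply: float
    maintenance_root: float
    maintenance_shoot: float
    shoot_alloc: float
    axial_alloc: float
    lateral_alloc: float
    to_reserve: float
    maintenance_deficit: bool = False


def co2_factor(co2: float, params: PlantParams) -> float:
    """Saturating CO2 response of the carbon source, 1 at the reference ppm."""
    if co2 <= 0:
        raise ValueError("co2 must be > 0")
    ref = params.co2_reference / (params.co2_reference + params.co2_half_sat)
    return (co2 / (co2 + params.co2_half_sat)) / ref


def carbon_supply(
    leaf_area: float,
    co2: float,
    water_stress: float,
    n_stress: float,
    day: int,
    params: PlantParams,
    seed_reserve: float,
) -> tuple[float, float]:
    """Daily carbon source (g C d-1) and the seed draw included in it.

    Photosynthetic term: LUE x intercepted light x f_CO2 x stress factor,
    with stress factor min(1 - water_stress, 1 - n_stress).  Seed reserves
    are released linearly over the establishment window.
    """
    if not (0.0 <= water_stress <= 1.0 and 0.0 <= n_stress <= 1.0):
        raise ValueError("stress indices must be in [0, 1]")
    lai = leaf_area / params.ground_area
    f_int = 1.0 - np.exp(-params.k_light * lai)
    # the more limiting stress reduces the source, with a bounded impact:
    # even severely stressed leaves retain (1 - stress_impact) of capacity
    limiting = 1.0 - min(1.0 - water_stress, 1.0 - n_stress)
    stress_factor = 1.0 - params.stress_impact * limiting
    photo = (
        params.lue * params.par * params.ground_area * f_int
        * co2_factor(co2, params) * stress_factor
    )
    seed_draw = 0.0
    if day < params.seed_release_days and seed_reserve > 0:
        remaining_days = params.seed_release_days - day
        seed_draw = min(seed_reserve, seed_reserve / remaining_days)
    return photo + seed_draw, seed_draw


def allocate(
    supply: float,
    maintenance_root: float,
    maintenance_shoot: float,
    shoot_demand: float,
    axial_demand: float,
    lateral_demand: float,
) -> CarbonBudget:
    """Priority waterfall; exact accounting (parts sum to supply).

    Maintenance is paid first.  If supply cannot cover maintenance, the
    deficit flag is set and all growth allocations are zero (the engine
    draws the unpaid maintenance from reserve).
    """
    for name, v in [
        ("maintenance_root", maintenance_root),
        ("maintenance_shoot", maintenance_shoot),
        ("shoot_demand", shoot_demand),
        ("axial_demand", axial_demand),
        ("lateral_demand", lateral_demand),
    ]:
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    maint = maintenance_root + maintenance_shoot
    if supply < maint:
        return CarbonBudget(
            supply=supply,
            maintenance_root=maintenance_root,
            maintenance_shoot=maintenance_shoot,
            shoot_alloc=0.0, axial_alloc=0.0, lateral_alloc=0.0,
            to_reserve=supply - maint,  # negative: reserve draw
            maintenance_deficit=True,
        )
    rem = supply - maint
    shoot = min(rem, shoot_demand)
    rem -= shoot
    axial = min(rem, axial_demand)
    rem -= axial
    lateral = min(rem, lateral_demand)
    rem -= lateral
    return CarbonBudget(
        supply=supply,
        maintenance_root=maintenance_root,
        maintenance_shoot=maintenance_shoot,
        shoot_alloc=shoot,
        axial_alloc=axial,
        lateral_alloc=lateral,
        to_reserve=rem,
    )


def stress_index(u: float, o: float, m: float) -> float:
    """clamp(1 - (u - m)/(o - m), 0, 1); 0 = no stress, 1 = severe stress."""
    if o <= m:
        raise ValueError(f"optimal content {o} must exceed minimal content {m}")
    return float(np.clip(1.0 - (u - m) / (o - m), 0.0, 1.0))


def n_uptake(
    root_surface: np.ndarray,
    nitrate_conc: np.ndarray,
    dt: float,
    params: PlantParams,
) -> np.ndarray:
    """Michaelis-Menten nitrate uptake demand per node (umol).

    uptake_i = I_max * C_i / (K_m + C_i) * area_i * dt.  The soil solute
    step caps the realized uptake at each node's available mass.
    """
    conc = np.asarray(nitrate_conc, float)
    if np.any(conc < -1e-12):
        raise ValueError("concentrations must be >= 0")
    conc = np.maximum(conc, 0.0)
    return params.i_max * conc / (params.k_m + conc) * np.asarray(root_surface) * dt


def grow_shoot(state: PlantState, shoot_alloc: float, params: PlantParams) -> None:
    """Convert allocated carbon to shoot dry weight and leaf area."""
    if shoot_alloc < 0:
        raise ValueError("shoot_alloc must be >= 0")
    state.shoot_biomass += shoot_alloc / params.shoot_c_fraction
    state.leaf_area = params.sla * params.leaf_mass_fraction * state.shoot_biomass
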