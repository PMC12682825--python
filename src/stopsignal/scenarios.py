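"""Factorial experiment factory: enumerate and materialize scenario cells.

The full design crosses 49 phenotypes x 2 soils x 3 managements x 2 water
regimes x 3 CO2 levels x 2 replicates = 3528 cells.  ``materialize`` turns
one cell into runnable inputs:

* native       - unmodified profile, high initial mineral N, full
                 mineralization from the organic pool;
* cultivated_LN - eroded/compacted profile (half A horizon, half OM,
                 +10 % Db), a quarter of the native initial mineral N,
                 correspondingly low mineralization, irrigated when WW
                 (which leaches nitrate downward);
* cultivated_HN - cultivated_LN plus a fertilizer pulse at day 0 restoring
                 native-level mineral N in the top 20 cm.

WW keeps the daily surface input at 0.5 cm throughout; WS cuts it to zero
after day 10 with a drier initial topsoil, so the topsoil dries and hardens.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from . import soils as soils_mod
from .phenotypes import DEFAULT_LEVELS, Phenotype, phenotype_grid
from .plant import PlantParams
from .rootsys import RootClassParams, maize_default_classes
from .soil_dynamics import BoundaryForcing, N_POOL_PER_OM_PCT

__all__ = [
    "SOILS",
    "MANAGEMENTS",
    "WATERS",
    "CO2_LEVELS",
    "ScenarioConfig",
    "RunInputs",
    "enumerate_grid",
    "materialize",
]

SOILS = ("sandy_loam", "silt_loam")
MANAGEMENTS = ("native", "cultivated_LN", "cultivated_HN")
WATERS = ("WW", "WS")
CO2_LEVELS = (270.0, 402.9, 500.0)

#: Daily surface water input (cm d-1): irrigation/rain under WW comfortably
#: exceeds peak evapotranspiration; WS gets modest rain until the cutoff day.
WW_DAILY_INPUT = 0.6
WS_DAILY_INPUT = 0.5
WS_CUTOFF_DAY = 5
POTENTIAL_EVAPORATION = 0.2  # cm d-1
WS_DRY_TOPSOIL_DEPTH = 30.0  # cm initialized dry under water stress
WS_TOPSOIL_AVAILABILITY = 0.25  # initial plant-available fraction in that band

#: Initial mineral nitrate in solution (umol cm-3 water); cultivated soils
#: retain a quarter of the native store; the HN fertilizer pulse restores
#: native levels in the top FERTILIZER_DEPTH cm.
NATIVE_NITRATE_CONC = 4.0
CULTIVATED_NITRATE_FRACTION = 0.25
FERTILIZER_DEPTH = 20.0

HORIZON_DAYS = 40


class ScenarioError(ValueError):
    """Unknown factor level in a scenario configuration."""


@dataclass(frozen=True)
class ScenarioConfig:
    """One factorial cell; the seed is derived from the cell identity."""

    soil: str
    management: str
    water: str
    co2: float
    phenotype: Phenotype
    replicate: int = 1
    seed: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.soil not in SOILS:
            raise ScenarioError(f"unknown soil {self.soil!r}")
        if self.management not in MANAGEMENTS:
            raise ScenarioError(f"unknown management {self.management!r}")
        if self.water not in WATERS:
            raise ScenarioError(f"unknown water regime {self.water!r}")
        if self.seed < 0:
            object.__setattr__(self, "seed", cell_seed(self))

    @property
    def cell_id(self) -> str:
        return (
            f"{self.soil}|{self.management}|{self.water}|{self.co2:g}|"
            f"{self.phenotype.label}|rep{self.replicate}"
        )


def cell_seed(config: ScenarioConfig, salt: int = 0) -> int:
    """Stable 31-bit seed from the cell identity (replicates differ by seed)."""
    ident = (
        f"{config.soil}|{config.management}|{config.water}|{config.co2:g}|"
        f"{config.phenotype.label}|rep{config.replicate}|{salt}"
    )
    return zlib.crc32(ident.encode()) & 0x7FFFFFFF


def enumerate_grid(
    levels: tuple[float, ...] = DEFAULT_LEVELS,
    soils: tuple[str, ...] = SOILS,
    managements: tuple[str, ...] = MANAGEMENTS,
    waters: tuple[str, ...] = WATERS,
    co2_levels: tuple[float, ...] = CO2_LEVELS,
    replicates: int = 2,
    salt: int = 0,
) -> list[ScenarioConfig]:
    """Full Cartesian product in deterministic order with per-cell seeds."""
    for name, seq in [
        ("levels", levels), ("soils", soils), ("managements", managements),
        ("waters", waters), ("co2_levels", co2_levels),
    ]:
        if not seq:
            raise ScenarioError(f"{name} must be non-empty")
    phenos = phenotype_grid(levels)
    configs = []
    for soil, mgmt, water, co2, pheno, rep in product(
        soils, managements, waters, co2_levels, phenos, range(1, replicates + 1)
    ):
        cfg = ScenarioConfig(soil, mgmt, water, co2, pheno, rep, seed=0)
        object.__setattr__(cfg, "seed", cell_seed(cfg, salt))
        configs.append(cfg)
    return configs


@dataclass
class RunInputs:
    """Fully resolved inputs for one simulation run."""

    config: ScenarioConfig
    profile: soils_mod.SoilProfile
    forcing: BoundaryForcing
    theta_init: np.ndarray
    nitrate_conc_init: np.ndarray
    mineralizable_N: np.ndarray
    plant_params: PlantParams
    root_classes: dict[str, RootClassParams]
    horizon: int = HORIZON_DAYS


def _native_profile(soil: str, grid_dz: float) -> soils_mod.SoilProfile:
    if soil == "sandy_loam":
        return soils_mod.sandy_loam_profile(grid_dz)
    return soils_mod.silt_loam_profile(grid_dz)


def materialize(
    config: ScenarioConfig,
    grid_dz: float = 2.0,
    horizon: int = HORIZON_DAYS,
    plant_params: PlantParams | None = None,
    root_classes: dict[str, RootClassParams] | None = None,
) -> RunInputs:
    """Resolve a scenario cell into a profile, forcing and initial states."""
    profile = _native_profile(config.soil, grid_dz)
    if config.management in ("cultivated_LN", "cultivated_HN"):
        profile = soils_mod.cultivate(profile)

    n = profile.n_nodes
    days = horizon + 1
    if config.water == "WW":
        rain = np.full(days, WW_DAILY_INPUT)
        theta0 = profile.theta_fc.copy()
    else:
        rain = np.where(np.arange(days) < WS_CUTOFF_DAY, WS_DAILY_INPUT, 0.0)
        theta0 = profile.theta_fc.copy()
        topsoil = profile.node_depths <= WS_DRY_TOPSOIL_DEPTH
        theta0[topsoil] = (
            profile.theta_pwp
            + WS_TOPSOIL_AVAILABILITY * (profile.theta_fc - profile.theta_pwp)
        )[topsoil]

    if config.management == "native":
        precipitation, irrigation = rain, np.zeros(days)
        conc0 = np.full(n, NATIVE_NITRATE_CONC)
    else:
        precipitation, irrigation = np.zeros(days), rain
        conc0 = np.full(n, NATIVE_NITRATE_CONC * CULTIVATED_NITRATE_FRACTION)
        if config.management == "cultivated_HN":
            top = profile.node_depths <= FERTILIZER_DEPTH
            conc0[top] = NATIVE_NITRATE_CONC

    forcing = BoundaryForcing(
        precipitation=precipitation,
        irrigation=irrigation,
        potential_evaporation=POTENTIAL_EVAPORATION,
    )
    return RunInputs(
        config=config,
        profile=profile,
        forcing=forcing,
        theta_init=theta0,
        nitrate_conc_init=conc0,
        mineralizable_N=N_POOL_PER_OM_PCT * profile.organic_matter.copy(),
        plant_params=plant_params or PlantParams(),
        root_classes=root_classes or maize_default_classes(),
        horizon=horizon,
    )
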