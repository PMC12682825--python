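"""Daily coupling of soil, root and plant modules over the 40-day horizon.

The coupling order is a fixed contract (COUPLING_ORDER):

1. update penetration resistance from the current water content;
2. plant carbon supply and the allocation waterfall;
3. root elongation (using the PR of step 1) and branching;
4. transpiration sink partitioning and Richards sub-stepping;
5. nitrate mineralization, uptake and convection-dispersion;
6. plant state and stress update.

Runs are deterministic for a fixed config+seed.  Mass balances (water,
nitrate, carbon) are accumulated every day and validated at the end of the
run; a breach raises EngineError naming the day.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import plant as plant_mod
from . import rootsys as root_mod
from . import soil_dynamics as sdyn
from .plant import PlantParams, PlantState, UMOL_PER_G_N
from .scenarios import RunInputs, ScenarioConfig, materialize

__all__ = ["COUPLING_ORDER", "SimulationRun", "EngineError", "run", "run_inputs"]

COUPLING_ORDER = (
    "penetration_resistance",
    "carbon_supply_and_allocation",
    "root_growth_and_branching",
    "water_uptake_and_richards",
    "nitrate_mineralization_transport_uptake",
    "plant_state_and_stress_update",
)

WATER_BALANCE_TOL_FRACTION = 0.005  # of cumulative throughput over the run
CARBON_CLOSURE_TOL = 1e-6  # relative


class EngineError(RuntimeError):
    """A module failure or balance breach during a run."""


@dataclass
class SimulationRun:
    """Trajectory and summaries of one simulated scenario cell."""

    config: ScenarioConfig
    horizon: int
    inputs: RunInputs
    plant_table: pd.DataFrame
    theta_hist: np.ndarray  # (horizon+1, n_nodes)
    pr_hist: np.ndarray
    nitrate_conc_hist: np.ndarray
    rld_hist: np.ndarray  # root length (cm) per node
    root_system: root_mod.RootSystem
    soil_state: sdyn.SoilState
    plant_state: PlantState
    water_balance: dict = field(default_factory=dict)
    nitrogen_balance: dict = field(default_factory=dict)
    carbon_balance: dict = field(default_factory=dict)

    @property
    def n_snapshots(self) -> int:
        return self.theta_hist.shape[0]

    def final_rld(self) -> np.ndarray:
        return self.rld_hist[-1]

    def metrics_hash(self) -> int:
        """Order-sensitive digest of the run's headline outputs."""
        import hashlib

        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.rld_hist).tobytes())
        h.update(np.ascontiguousarray(self.theta_hist).tobytes())
        h.update(self.plant_table.to_csv(float_format="%.12e").encode())
        return int.from_bytes(h.digest()[:8], "big")


def run_inputs(inputs: RunInputs) -> SimulationRun:
    """Run the daily loop on fully materialized inputs."""
    cfg = inputs.config
    profile = inputs.profile
    pp: PlantParams = inputs.plant_params
    horizon = inputs.horizon
    n = profile.n_nodes
    dz = profile.grid_dz
    area = pp.ground_area

    system = root_mod.initialize_root_system(
        inputs.root_classes, seed=cfg.seed, domain_depth=profile.total_depth
    )
    soil = sdyn.initialize_state(
        profile, inputs.theta_init, inputs.nitrate_conc_init, inputs.mineralizable_N
    )
    plant = PlantState(
        shoot_biomass=pp.initial_shoot_dw,
        leaf_area=pp.sla * pp.leaf_mass_fraction * pp.initial_shoot_dw,
        seed_reserve=pp.seed_reserve,
        plant_N=pp.initial_plant_n,
    )

    # incremental depth profiles of root length and surface area
    rld = np.zeros(n)
    surf = np.zeros(n)
    _, _, circ = system.class_param_arrays()

    def absorb_blocks(start_block: int) -> None:
        nonlocal rld, surf
        for b in system.seg_blocks[start_block:]:
            bz, tz, ln, cc = b["base"][:, 2], b["tip"][:, 2], b["length"], b["class_code"]
            rld += root_mod.apportion_to_nodes(bz, tz, ln, n, dz)
            surf += root_mod.apportion_to_nodes(bz, tz, ln * circ[cc], n, dz)

    absorb_blocks(0)

    theta_hist = np.empty((horizon + 1, n))
    pr_hist = np.empty((horizon + 1, n))
    conc_hist = np.empty((horizon + 1, n))
    rld_hist = np.empty((horizon + 1, n))

    soil.PR = profile.penetration_resistance_nodes(soil.theta)
    theta_hist[0] = soil.theta
    pr_hist[0] = soil.PR
    conc_hist[0] = soil.nitrate_conc(profile)
    rld_hist[0] = rld

    rows = []
    supply_total = 0.0
    seed_drawn_total = 0.0
    theta_start = soil.theta.copy()
    nitrate_start = float(soil.nitrate_mass.sum())
    infil_total = evap_total = transp_total = 0.0
    n_uptake_total = mineralized_total = 0.0

    for day in range(horizon):
        try:
            # (1) penetration resistance from current water content
            soil.PR = profile.penetration_resistance_nodes(soil.theta)

            # (2) carbon supply and allocation
            ws_s, ns_s = plant.smoothed_stresses(pp.stress_window)
            supply, seed_draw = plant_mod.carbon_supply(
                plant.leaf_area, cfg.co2, ws_s, ns_s, day, pp, plant.seed_reserve
            )
            plant.seed_reserve -= seed_draw
            root_c = system.carbon_construction
            shoot_c = plant.shoot_biomass * pp.shoot_c_fraction
            maint_root = pp.maintenance_root * root_c
            maint_shoot = pp.maintenance_shoot * shoot_c
            # shoot sink capacity is bounded by a fixed share of the net
            # source (functional balance): strict shoot priority would
            # otherwise starve roots whenever demand outruns supply
            shoot_demand = min(
                pp.shoot_rgr * shoot_c,
                pp.shoot_supply_fraction * max(supply - maint_root - maint_shoot, 0.0),
            )
            dl_pot, growth_cost, axial_mask = root_mod.growth_potential(
                system, soil.PR, profile.node_of_depth, cfg.phenotype, dt=1.0
            )
            axial_demand = float(growth_cost[axial_mask].sum())
            lateral_demand = float(growth_cost[~axial_mask].sum())
            budget = plant_mod.allocate(
                supply, maint_root, maint_shoot, shoot_demand, axial_demand, lateral_demand
            )

            # (3) root elongation and branching
            block_start = len(system.seg_blocks)
            root_alloc = budget.axial_alloc + budget.lateral_alloc
            carbon_used = root_mod.elongate_roots(
                system, soil.PR, profile.node_of_depth, cfg.phenotype,
                root_alloc, dt=1.0, day=day,
            )
            root_mod.emit_branches(system, day + 1)
            absorb_blocks(block_start)

            # (4) transpiration sink and Richards sub-stepping
            pot_transp_cm = pp.transpiration_per_leaf * plant.leaf_area / area
            sink, actual_transp_rate = sdyn.water_uptake_sink(
                rld, soil, profile, pot_transp_cm,
                max_uptake_per_cm=pp.max_uptake_per_cm / area,
            )
            wdiag = sdyn.advance_water(
                soil, profile, sink,
                surface_input=inputs.forcing.surface_input(day),
                potential_evaporation=inputs.forcing.potential_evaporation,
            )

            # (5) nitrate: mineralization, uptake demand, transport
            mineralized_total += sdyn.mineralize(soil, profile, dt=1.0, t=float(day))
            conc = soil.nitrate_conc(profile)
            demand_n = plant_mod.n_uptake(surf / area, conc, dt=1.0, params=pp)
            ndiag = sdyn.nitrate_step(
                soil, profile,
                q_faces=wdiag["q_faces_mean"],
                q_top=wdiag["infiltration"] - wdiag["evaporation"],
                q_bot=wdiag["drainage"],
                uptake_N=demand_n,
                dt=1.0,
                c_in=inputs.forcing.nitrate_in_infiltration,
            )

            # (6) plant state and stress update
            plant_mod.grow_shoot(plant, budget.shoot_alloc, pp)
            system.carbon_maintenance += maint_root
            plant.reserve += budget.to_reserve + (root_alloc - carbon_used)
            plant.cum_water_uptake += wdiag["transpiration"] * area
            plant.cum_potential_transpiration += pot_transp_cm * area
            plant.plant_N += ndiag["uptake"] * area
            plant.cum_n_uptake += ndiag["uptake"] * area

            o_w = plant.cum_potential_transpiration
            m_w = pp.water_minimal_fraction * o_w
            if o_w > 1e-9:
                plant.water_stress = plant_mod.stress_index(plant.cum_water_uptake, o_w, m_w)
            else:
                plant.water_stress = 0.0
            o_n = pp.n_optimal_pct / 100.0 * plant.shoot_biomass * UMOL_PER_G_N
            m_n = pp.n_minimal_pct / 100.0 * plant.shoot_biomass * UMOL_PER_G_N
            plant.n_stress = plant_mod.stress_index(plant.plant_N, o_n, m_n)
            plant.water_stress_history.append(plant.water_stress)
            plant.n_stress_history.append(plant.n_stress)

            supply_total += supply
            seed_drawn_total += seed_draw
            infil_total += wdiag["infiltration"]
            evap_total += wdiag["evaporation"]
            transp_total += wdiag["transpiration"]
            n_uptake_total += ndiag["uptake"]

            theta_hist[day + 1] = soil.theta
            pr_hist[day + 1] = profile.penetration_resistance_nodes(soil.theta)
            conc_hist[day + 1] = soil.nitrate_conc(profile)
            rld_hist[day + 1] = rld

            rows.append(
                dict(
                    day=day + 1,
                    shoot_dw=plant.shoot_biomass,
                    leaf_area=plant.leaf_area,
                    supply=supply,
                    seed_draw=seed_draw,
                    shoot_alloc=budget.shoot_alloc,
                    axial_alloc=budget.axial_alloc,
                    lateral_alloc=budget.lateral_alloc,
                    maintenance=maint_root + maint_shoot,
                    root_construction=carbon_used,
                    water_stress=plant.water_stress,
                    n_stress=plant.n_stress,
                    pot_transpiration_cm=pot_transp_cm,
                    transpiration_cm=wdiag["transpiration"],
                    n_uptake_umol=ndiag["uptake"] * area,
                    root_carbon=system.carbon_invested,
                    root_length=system.total_length,
                    max_root_depth=system.max_tip_depth(),
                )
            )
        except (sdyn.SolverError, ValueError) as exc:
            raise EngineError(f"day {day}: {exc}") from exc

    table = pd.DataFrame(rows)

    # ---- run-level balance audits --------------------------------------
    d_storage = float((soil.theta - theta_start).sum() * dz)
    water_in = infil_total
    water_out = evap_total + transp_total + soil.cumulative_drainage_water
    water_residual = d_storage - (water_in - water_out)
    throughput = max(water_in + water_out, 1e-9)
    water_balance = dict(
        storage_change=d_storage, infiltration=water_in, evaporation=evap_total,
        transpiration=transp_total, drainage=soil.cumulative_drainage_water,
        residual=water_residual, relative_residual=abs(water_residual) / throughput,
    )
    if abs(water_residual) > WATER_BALANCE_TOL_FRACTION * throughput:
        raise EngineError(
            f"water balance residual {water_residual:.3e} cm exceeds "
            f"{WATER_BALANCE_TOL_FRACTION:%} of throughput"
        )

    nitrate_end = float(soil.nitrate_mass.sum())
    n_residual = nitrate_end - (
        nitrate_start + mineralized_total - n_uptake_total - soil.cumulative_drainage_N
    )
    n_throughput = max(nitrate_start + mineralized_total, 1e-9)
    nitrogen_balance = dict(
        initial=nitrate_start, mineralized=mineralized_total, uptake=n_uptake_total,
        drained=soil.cumulative_drainage_N, final=nitrate_end,
        residual=n_residual, relative_residual=abs(n_residual) / n_throughput,
    )
    if abs(n_residual) > WATER_BALANCE_TOL_FRACTION * n_throughput:
        raise EngineError(f"nitrate balance residual {n_residual:.3e} umol cm-2")

    shoot_c_growth = (plant.shoot_biomass - pp.initial_shoot_dw) * pp.shoot_c_fraction
    # carbon ledger: supply = shoot growth + root construction + maintenance + reserve
    carbon_spent = (
        shoot_c_growth
        + (system.carbon_construction - _initial_root_carbon(system))
        + float(table["maintenance"].sum())
        + plant.reserve
    )
    carbon_residual = supply_total - carbon_spent
    carbon_balance = dict(
        supply=supply_total, seed_draw=seed_drawn_total, shoot_growth=shoot_c_growth,
        root_construction=system.carbon_construction - _initial_root_carbon(system),
        maintenance=float(table["maintenance"].sum()), reserve=plant.reserve,
        residual=carbon_residual,
        relative_residual=abs(carbon_residual) / max(supply_total, 1e-12),
    )
    if abs(carbon_residual) > CARBON_CLOSURE_TOL * max(supply_total, 1e-9):
        raise EngineError(f"carbon closure residual {carbon_residual:.3e} g C")

    return SimulationRun(
        config=cfg,
        horizon=horizon,
        inputs=inputs,
        plant_table=table,
        theta_hist=theta_hist,
        pr_hist=pr_hist,
        nitrate_conc_hist=conc_hist,
        rld_hist=rld_hist,
        root_system=system,
        soil_state=soil,
        plant_state=plant,
        water_balance=water_balance,
        nitrogen_balance=nitrogen_balance,
        carbon_balance=carbon_balance,
    )


def _initial_root_carbon(system: root_mod.RootSystem) -> float:
    """Construction carbon of the germination segment (not supplied by the
    daily source; it comes with the seed)."""
    p = system.classes["primary"]
    return system.segment_quantum * p.cost_per_cm


def run(config: ScenarioConfig, **materialize_kwargs) -> SimulationRun:
    """Materialize a scenario cell and run it."""
    return run_inputs(materialize(config, **materialize_kwargs))
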