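"""1-D vertical soil water and nitrate dynamics with root sinks.

Water moves by the Richards equation on a node-centered finite-volume grid
(z positive downward), solved implicitly with modified-Picard iteration and
a banded tridiagonal solve; the surface carries a flux boundary
(infiltration - evaporation) and the bottom is free drainage.  Nitrate
moves by convection-dispersion (upwinded, explicit with CFL sub-steps) on
the Darcy fluxes of the same interval, with mineral-N release from a
declining-rate organic pool and Michaelis-Menten root uptake applied by the
engine.  All state is per unit ground area: water in cm, solute in umol cm-2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded

from .soils import SoilProfile

__all__ = [
    "SoilState",
    "BoundaryForcing",
    "SolverError",
    "initialize_state",
    "richards_step",
    "advance_water",
    "water_uptake_sink",
    "nitrate_step",
    "mineralize",
    "water_availability",
]

# Solute transport defaults: molecular diffusion (cm2 d-1), dispersivity (cm).
D0_DEFAULT = 1.5
DISPERSIVITY_DEFAULT = 2.0

# Mineralization defaults: first-order rate that declines with time since
# the start of the season, k(t) = k1 * (t+1)^(-q); pool scales with OM.
MINERALIZATION_K1 = 0.01  # d-1
MINERALIZATION_Q = 0.5
N_POOL_PER_OM_PCT = 6.0  # umol mineralizable N per cm3 soil per % OM


class SolverError(RuntimeError):
    """Richards iteration failed to converge at the minimum sub-step."""


@dataclass
class BoundaryForcing:
    """Daily surface forcing series (cm d-1), indexable by day."""

    precipitation: np.ndarray
    irrigation: np.ndarray
    potential_evaporation: float = 0.2
    nitrate_in_infiltration: float = 0.0  # umol cm-3 of infiltrating water

    def surface_input(self, day: int) -> float:
        return float(self.precipitation[day] + self.irrigation[day])


@dataclass
class SoilState:
    """Per-node soil state plus cumulative boundary fluxes."""

    theta: np.ndarray
    head: np.ndarray
    nitrate_mass: np.ndarray  # umol cm-2 per node (solute in solution)
    mineralizable_N: np.ndarray  # umol cm-3 soil
    PR: np.ndarray  # kPa
    cumulative_drainage_water: float = 0.0
    cumulative_drainage_N: float = 0.0
    cumulative_infiltration: float = 0.0
    cumulative_evaporation: float = 0.0
    cumulative_mineralized_N: float = 0.0

    def nitrate_conc(self, profile: SoilProfile) -> np.ndarray:
        """Solution concentration (umol cm-3 water)."""
        return self.nitrate_mass / np.maximum(self.theta * profile.grid_dz, 1e-12)


def initialize_state(
    profile: SoilProfile,
    theta: np.ndarray,
    nitrate_conc: np.ndarray,
    mineralizable_N: np.ndarray | None = None,
) -> SoilState:
    theta = np.clip(np.asarray(theta, float), profile.theta_r + 1e-9, profile.theta_s)
    head = profile.head_of_theta(theta)
    mass = np.asarray(nitrate_conc, float) * theta * profile.grid_dz
    if mineralizable_N is None:
        mineralizable_N = N_POOL_PER_OM_PCT * profile.organic_matter.copy()
    return SoilState(
        theta=theta,
        head=head,
        nitrate_mass=mass,
        mineralizable_N=np.asarray(mineralizable_N, float).copy(),
        PR=profile.penetration_resistance_nodes(theta),
    )


def water_availability(theta: np.ndarray, profile: SoilProfile) -> np.ndarray:
    """Plant-available water fraction: 0 at wilting point, 1 at field capacity."""
    return np.clip(
        (theta - profile.theta_pwp) / (profile.theta_fc - profile.theta_pwp), 0.0, 1.0
    )


def _face_conductivity(K: np.ndarray) -> np.ndarray:
    return 0.5 * (K[:-1] + K[1:])


def richards_step(
    state: SoilState,
    profile: SoilProfile,
    sink: np.ndarray,
    q_top: float,
    dt: float,
    bottom: str = "free_drainage",
    max_iter: int = 60,
    tol_theta: float = 1e-6,
    tol_theta_fallback: float = 2e-5,
) -> dict:
    """One implicit Richards step; mutates theta/head, returns diagnostics.

    ``sink`` is water extraction per node (cm d-1), ``q_top`` the prescribed
    surface flux (cm d-1, positive downward/into the soil).  Uses the
    mass-conservative modified Picard linearization; raises SolverError if
    the iteration does not converge (caller halves dt).
    """
    dz = profile.grid_dz
    n = profile.n_nodes
    h_old = state.head.copy()
    theta_old = state.theta.copy()
    h = h_old.copy()
    sink_vol = np.asarray(sink, float) / dz  # cm d-1 per node -> d-1 (volumetric)

    # storativity floor keeps the system regular when a node saturates
    ss = 1e-7
    best_dtheta = np.inf
    best = None

    for it in range(max_iter):
        theta_k = profile.theta_of_head(h)
        C = profile.capacity_of_head(h) + ss
        K = profile.K_of_head(h)
        Kf = _face_conductivity(K)  # faces between nodes, size n-1
        q_bot = float(K[-1]) if bottom == "free_drainage" else 0.0

        # tridiagonal assembly: a h[i-1] + b h[i] + c h[i+1] = r
        a = np.zeros(n)
        b = np.zeros(n)
        c = np.zeros(n)
        r = np.zeros(n)

        b[:] = C / dt
        r[:] = C / dt * h - (theta_k - theta_old) / dt - sink_vol

        # interior faces: q_face = -Kf * ((h[i+1]-h[i])/dz - 1), positive down
        # divergence for node i: (q_in - q_out)/dz
        upper = Kf / dz**2
        a[1:] -= upper
        b[1:] += upper
        b[:-1] += upper
        c[:-1] -= upper
        # gravity contributions of the faces
        r[:-1] -= Kf / dz
        r[1:] += Kf / dz

        # boundaries
        r[0] += q_top / dz
        r[-1] -= q_bot / dz

        ab = np.zeros((3, n))
        ab[0, 1:] = c[:-1]
        ab[1, :] = b
        ab[2, :-1] = a[1:]
        h_new = solve_banded((1, 1), ab, r)

        dtheta = float(np.max(np.abs(profile.theta_of_head(h_new) - theta_k)))
        # mass-conservative update candidate: water content from the
        # linearized storage term of this solve, so the discrete balance
        # telescopes exactly (h stays the auxiliary variable)
        candidate = (theta_k + C * (h_new - h), h_new.copy(), Kf, q_bot)
        if dtheta < best_dtheta:
            best_dtheta, best = dtheta, candidate
        if dtheta < tol_theta:
            break
        # damp later iterations: sharp wetting fronts and perched
        # saturation make undamped Picard oscillate or limit-cycle
        h = h_new if it < 8 else (0.7 * h_new + 0.3 * h if it < 20 else 0.3 * h_new + 0.7 * h)
    else:
        # at perched saturated fronts the iteration can limit-cycle with a
        # tiny theta amplitude; accept the best iterate if it is close
        if best_dtheta >= tol_theta_fallback:
            raise SolverError(
                f"Richards Picard iteration did not converge (dt={dt} d, "
                f"best residual {best_dtheta:.2e})"
            )
    theta_new, h, Kf, q_bot = best

    q_faces = -Kf * ((h[1:] - h[:-1]) / dz - 1.0)

    # keep water contents physical (clip amounts are O(storativity floor))
    theta_new = np.clip(theta_new, profile.theta_r, profile.theta_s)

    d_storage = float((theta_new - theta_old).sum() * dz)
    balance_error = d_storage - (q_top - q_bot - float(sink.sum())) * dt

    state.head = h
    state.theta = theta_new
    state.cumulative_drainage_water += q_bot * dt

    return dict(
        q_top=q_top,
        q_bot=q_bot,
        q_faces=q_faces,
        balance_error=balance_error,
        transpired=float(sink.sum()) * dt,
    )


def advance_water(
    state: SoilState,
    profile: SoilProfile,
    sink: np.ndarray,
    surface_input: float,
    potential_evaporation: float,
    dt_total: float = 1.0,
    dt_init: float = 0.05,
    dt_min: float = 1e-4,
    bottom: str = "free_drainage",
    balance_tol: float = 1e-4,
) -> dict:
    """Advance water over dt_total with adaptive sub-steps.

    Evaporation is demand-limited by topsoil water availability and, with
    uptake, capped so no node is driven below wilting point by the sinks.
    Returns day-integrated fluxes and the time-averaged internode Darcy
    fluxes needed by the solute step.
    """
    dz = profile.grid_dz
    t = 0.0
    dt = dt_init
    q_faces_acc = np.zeros(profile.n_nodes - 1)
    actual_evap = 0.0
    actual_transp = 0.0
    drainage0 = state.cumulative_drainage_water
    balance_acc = 0.0

    # evaporation extracts from a shallow surface layer (evaporation front),
    # weighted exponentially with depth; each node's share ramps down toward
    # an air-dry limit midway between residual and wilting point, so the
    # topsoil - not just the surface node - dries below wilting and hardens
    z_e = 12.0  # cm, depth of the evaporation layer
    w_evap = np.where(
        profile.node_depths <= z_e, np.exp(-profile.node_depths / 4.0), 0.0
    )
    w_evap = w_evap / w_evap.sum()
    theta_air_dry = 0.5 * (profile.theta_r + profile.theta_pwp)

    while t < dt_total - 1e-12:
        dt = min(dt, dt_total - t)
        evap_avail = np.clip(
            (state.theta - theta_air_dry) / (profile.theta_fc - theta_air_dry),
            0.0, 1.0,
        )
        evap_sink = potential_evaporation * w_evap * evap_avail
        evap = float(evap_sink.sum())
        q_top = surface_input
        # cap sinks so they cannot push a node below wilting point this sub-step
        headroom = np.maximum(state.theta - profile.theta_pwp, 0.0) * dz / dt
        transp_sink = np.minimum(sink, headroom)
        sink_eff = transp_sink + evap_sink
        saved = (state.theta.copy(), state.head.copy(), state.cumulative_drainage_water)
        try:
            diag = richards_step(state, profile, sink_eff, q_top, dt, bottom=bottom)
        except SolverError:
            state.theta, state.head, state.cumulative_drainage_water = saved
            if dt / 2.0 < dt_min:
                raise
            dt /= 2.0
            continue
        if abs(diag["balance_error"]) > balance_tol:
            state.theta, state.head, state.cumulative_drainage_water = saved
            if dt / 2.0 < dt_min:
                raise SolverError(
                    f"water balance error {diag['balance_error']:.2e} cm at minimum sub-step"
                )
            dt /= 2.0
            continue
        q_faces_acc += diag["q_faces"] * dt
        actual_evap += evap * dt
        actual_transp += float(transp_sink.sum()) * dt
        balance_acc += diag["balance_error"]
        t += dt
        dt = min(dt * 1.5, dt_init)

    state.cumulative_infiltration += surface_input * dt_total
    state.cumulative_evaporation += actual_evap
    return dict(
        infiltration=surface_input * dt_total,
        evaporation=actual_evap,
        transpiration=actual_transp,
        drainage=state.cumulative_drainage_water - drainage0,
        q_faces_mean=q_faces_acc / dt_total,
        balance_error=balance_acc,
    )


def water_uptake_sink(
    root_length: np.ndarray,
    state: SoilState,
    profile: SoilProfile,
    demand: float,
    max_uptake_per_cm: float = 0.0,
) -> tuple[np.ndarray, float]:
    """Partition transpiration demand (cm d-1) over nodes.

    Weights are proportional to root length x plant-available water
    (a ramp from 0 at wilting point to 1 at field capacity).  Each node is
    additionally capped by its extractable water and, when
    ``max_uptake_per_cm`` > 0 (cm water column per cm root per day), by a
    root-uptake rate limit so sparse deep roots cannot satisfy unlimited
    demand.  Returns (per-node uptake cm d-1, actual transpiration cm d-1).
    """
    if demand < 0:
        raise ValueError("demand must be >= 0")
    avail = water_availability(state.theta, profile)
    w = root_length * avail
    total = w.sum()
    if total <= 0 or demand == 0:
        return np.zeros_like(w), 0.0
    uptake = demand * w / total
    cap = np.maximum(state.theta - profile.theta_pwp, 0.0) * profile.grid_dz
    if max_uptake_per_cm > 0:
        # per-root capacity falls with availability squared: soil hydraulic
        # conductivity around roots collapses in drying soil, so dense roots
        # in dry layers extract little even when some water remains
        cap = np.minimum(cap, max_uptake_per_cm * root_length * avail**2)
    uptake = np.minimum(uptake, cap)
    return uptake, float(uptake.sum())


def nitrate_step(
    state: SoilState,
    profile: SoilProfile,
    q_faces: np.ndarray,
    q_top: float,
    q_bot: float,
    uptake_N: np.ndarray,
    dt: float,
    c_in: float = 0.0,
    D0: float = D0_DEFAULT,
    dispersivity: float = DISPERSIVITY_DEFAULT,
) -> dict:
    """Convection-dispersion of nitrate on the day's Darcy fluxes.

    Explicit finite volume with upwinded advection and Millington-Quirk
    tortuosity for effective diffusion; CFL-limited sub-steps.  ``uptake_N``
    (umol cm-2 per node, already capped by the caller against available
    mass) is removed first.  Nitrate leaving the bottom face accumulates in
    ``cumulative_drainage_N``.  Mass balance closes to machine precision by
    construction; the closure is returned for verification.
    """
    dz = profile.grid_dz
    mass0 = float(state.nitrate_mass.sum())

    uptake = np.minimum(np.asarray(uptake_N, float), state.nitrate_mass)
    if np.any(uptake < -1e-12):
        raise ValueError("uptake_N must be >= 0")
    state.nitrate_mass = state.nitrate_mass - uptake
    taken = float(uptake.sum())

    theta = state.theta
    v = q_faces / np.maximum(0.5 * (theta[:-1] + theta[1:]), 1e-9)
    tau = theta ** (7.0 / 3.0) / profile.theta_s**2
    De = D0 * 0.5 * (tau[:-1] + tau[1:]) + dispersivity * np.abs(v)
    theta_f = 0.5 * (theta[:-1] + theta[1:])

    # stable sub-step: advection CFL and explicit diffusion limit
    with np.errstate(divide="ignore"):
        dt_adv = np.min(np.where(np.abs(q_faces) > 1e-12,
                                 0.4 * dz * np.minimum(theta[:-1], theta[1:])
                                 / np.maximum(np.abs(q_faces), 1e-12), np.inf))
        dt_dif = np.min(np.where(De > 1e-12,
                                 0.4 * dz**2 * np.minimum(theta[:-1], theta[1:])
                                 / np.maximum(De * theta_f, 1e-12), np.inf))
    dt_bot = 0.4 * dz * theta[-1] / max(q_bot, 1e-12)
    dt_sub = min(dt_adv, dt_dif, dt_bot, dt)
    n_sub = max(int(np.ceil(dt / dt_sub)), 1)
    dt_sub = dt / n_sub

    drained = 0.0
    inflow = max(q_top, 0.0) * c_in * dt
    state.nitrate_mass[0] += inflow

    for _ in range(n_sub):
        conc = state.nitrate_mass / np.maximum(theta * dz, 1e-12)
        c_up = np.where(q_faces >= 0.0, conc[:-1], conc[1:])
        flux = q_faces * c_up - De * theta_f * (conc[1:] - conc[:-1]) / dz
        bottom_flux = max(q_bot, 0.0) * conc[-1]
        dm = np.zeros_like(state.nitrate_mass)
        dm[:-1] -= flux * dt_sub
        dm[1:] += flux * dt_sub
        dm[-1] -= bottom_flux * dt_sub
        state.nitrate_mass = np.maximum(state.nitrate_mass + dm, 0.0)
        drained += bottom_flux * dt_sub

    state.cumulative_drainage_N += drained
    mass1 = float(state.nitrate_mass.sum())
    closure = mass1 - (mass0 - taken + inflow - drained)
    return dict(uptake=taken, drained=drained, inflow=inflow, closure=closure)


def mineralize(
    state: SoilState,
    profile: SoilProfile,
    dt: float,
    t: float,
    k1: float = MINERALIZATION_K1,
    q_exp: float = MINERALIZATION_Q,
) -> float:
    """Release mineral N from the organic pool at a declining specific rate.

    dN = pool * k1 * (t+1)^(-q) * dt per node; the released N enters the
    nitrate solution mass of the node.  Returns total release (umol cm-2).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    rate = k1 * (t + 1.0) ** (-q_exp)
    release = state.mineralizable_N * min(rate * dt, 1.0)  # umol cm-3 soil
    state.mineralizable_N = state.mineralizable_N - release
    released_mass = release * profile.grid_dz
    state.nitrate_mass = state.nitrate_mass + released_mass
    total = float(released_mass.sum())
    state.cumulative_mineralized_N += total
    return total
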