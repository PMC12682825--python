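"""Summary metrics of a run and the phenotype fitness-landscape tables.

D95 is the soil depth above which 95 % of root length is located (linear
interpolation within the containing grid cell).  Depth-band fractions
contrast topsoil (<= 30 cm) against deep soil (> 60 cm).  Water-class
fractions bin root length by plant-available water at the root surface
(low < 0.25, mid, high > 0.75 of the available range by default).  The
landscape table arranges shoot dry weight at the end of the run over the
(a_axial, a_lateral) grid and reports the argmax phenotype, ties broken
toward the smaller (more plastic) exponents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import SimulationRun
from .soil_dynamics import water_availability

__all__ = [
    "MetricsRow",
    "MetricUndefinedError",
    "compute_d95",
    "depth_band_fractions",
    "water_class_fractions",
    "water_per_carbon",
    "compute_metrics",
    "landscape_table",
]

WATER_CLASS_BOUNDS = (0.25, 0.75)
TOPSOIL_DEPTH = 30.0
DEEP_DEPTH = 60.0
WATER_PER_C_WINDOW = (20, 40)


class MetricUndefinedError(ValueError):
    """A metric is undefined for this input (e.g. zero root length)."""


@dataclass(frozen=True)
class MetricsRow:
    """Summarized outputs of one factorial cell."""

    soil: str
    management: str
    water: str
    co2: float
    a_axial: float
    a_lateral: float
    replicate: int
    seed: int
    d95: float
    max_root_depth: float
    frac_top30: float
    frac_below60: float
    frac_water_low: float
    frac_water_mid: float
    frac_water_high: float
    water_per_gC: float
    shoot_dw: float
    water_stress: float
    n_stress: float
    total_root_length: float
    root_carbon: float


def compute_d95(root_length: np.ndarray, node_depths: np.ndarray, dz: float) -> float:
    """Smallest depth above which >= 95 % of root length lies."""
    total = float(np.sum(root_length))
    if total <= 0:
        raise MetricUndefinedError("zero total root length")
    target = 0.95 * total
    cum = np.cumsum(root_length)
    i = int(np.searchsorted(cum, target))
    upper_edge = node_depths[i] + dz / 2.0
    prev = cum[i - 1] if i > 0 else 0.0
    within = root_length[i]
    if within <= 0:
        return float(upper_edge - dz)
    frac = (target - prev) / within
    return float(upper_edge - dz + frac * dz)


def depth_band_fractions(
    root_length: np.ndarray,
    node_depths: np.ndarray,
    dz: float,
    top: float = TOPSOIL_DEPTH,
    deep: float = DEEP_DEPTH,
) -> tuple[float, float]:
    """Fractions of total root length at depth <= top and depth > deep.

    Grid cells straddling a band edge contribute proportionally.
    """
    total = float(np.sum(root_length))
    if total <= 0:
        raise MetricUndefinedError("zero total root length")
    lo_edges = node_depths - dz / 2.0
    hi_edges = node_depths + dz / 2.0
    w_top = np.clip((np.minimum(hi_edges, top) - lo_edges) / dz, 0.0, 1.0)
    w_deep = np.clip((hi_edges - np.maximum(lo_edges, deep)) / dz, 0.0, 1.0)
    return float((root_length * w_top).sum() / total), float(
        (root_length * w_deep).sum() / total
    )


def water_class_fractions(
    root_length: np.ndarray,
    theta: np.ndarray,
    profile,
    bounds: tuple[float, float] = WATER_CLASS_BOUNDS,
) -> tuple[float, float, float]:
    """Root-length fractions in (low, mid, high) water-availability classes."""
    total = float(np.sum(root_length))
    if total <= 0:
        raise MetricUndefinedError("zero total root length")
    avail = water_availability(theta, profile)
    lo, hi = bounds
    low = float(root_length[avail < lo].sum() / total)
    high = float(root_length[avail > hi].sum() / total)
    return low, 1.0 - low - high, high


def water_per_carbon(run: SimulationRun, window: tuple[int, int] = WATER_PER_C_WINDOW) -> float:
    """Cumulative water uptake (cm3) per g C invested in roots over a window."""
    d0, d1 = window
    if not (0 <= d0 < d1 <= run.horizon):
        raise MetricUndefinedError(f"window {window} outside horizon {run.horizon}")
    t = run.plant_table
    sel = (t["day"] > d0) & (t["day"] <= d1)
    uptake = float(t.loc[sel, "transpiration_cm"].sum()) * run.inputs.plant_params.ground_area
    carbon = float(t.loc[t["day"] == d1, "root_carbon"].iloc[0])
    if carbon <= 0:
        raise MetricUndefinedError("zero root carbon")
    return uptake / carbon


def compute_metrics(run: SimulationRun) -> MetricsRow:
    """Summarize one finished run into a MetricsRow."""
    profile = run.inputs.profile
    rld = run.final_rld()
    d95 = compute_d95(rld, profile.node_depths, profile.grid_dz)
    top, deep = depth_band_fractions(rld, profile.node_depths, profile.grid_dz)
    low, mid, high = water_class_fractions(rld, run.theta_hist[-1], profile)
    cfg = run.config
    return MetricsRow(
        soil=cfg.soil,
        management=cfg.management,
        water=cfg.water,
        co2=cfg.co2,
        a_axial=cfg.phenotype.a_axial,
        a_lateral=cfg.phenotype.a_lateral,
        replicate=cfg.replicate,
        seed=cfg.seed,
        d95=d95,
        max_root_depth=run.root_system.max_tip_depth(),
        frac_top30=top,
        frac_below60=deep,
        frac_water_low=low,
        frac_water_mid=mid,
        frac_water_high=high,
        water_per_gC=water_per_carbon(run),
        shoot_dw=float(run.plant_table["shoot_dw"].iloc[-1]),
        water_stress=run.plant_state.water_stress,
        n_stress=run.plant_state.n_stress,
        total_root_length=run.root_system.total_length,
        root_carbon=run.root_system.carbon_invested,
    )


def landscape_table(rows) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Shoot-biomass fitness landscape over (a_axial, a_lateral).

    Accepts MetricsRow objects or an equivalent DataFrame for one scenario
    (one soil x management x water x co2 combination); replicates are
    averaged.  Returns (pivot table, argmax (a_axial, a_lateral)), ties
    broken toward the smaller exponent pair.  Missing cells raise with an
    explicit gap report rather than being imputed.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
    else:
        df = pd.DataFrame([r.__dict__ for r in rows])
    if df.empty:
        raise MetricUndefinedError("no rows supplied")
    mean = df.groupby(["a_axial", "a_lateral"], as_index=False)["shoot_dw"].mean()
    table = mean.pivot(index="a_axial", columns="a_lateral", values="shoot_dw")
    if table.isna().any().any():
        gaps = [
            (ax, al)
            for ax in table.index
            for al in table.columns
            if pd.isna(table.loc[ax, al])
        ]
        raise MetricUndefinedError(f"landscape has missing cells: {gaps}")
    best = table.stack()
    m = best.max()
    candidates = sorted(best[best >= m - 1e-12].index.tolist())
    return table, candidates[0]
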