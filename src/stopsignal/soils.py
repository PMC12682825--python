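"""Layered soil profiles, pedotransfer functions and penetration resistance.

A :class:`SoilProfile` is a contiguous stack of :class:`SoilLayer` objects
discretized onto a uniform vertical grid (z positive downward, cm).  Each
layer carries texture, bulk density and organic matter; hydraulic parameters
are derived per layer via the Saxton-Rawls (2006) pedotransfer regressions
and a two-point van Genuchten fit through field capacity (-33 kPa) and
permanent wilting point (-1500 kPa).

Soil strength (penetration resistance, PR) is computed dynamically from
water status and bulk density with a Whalley-type log-linear pedotransfer:

    log10(PR_kPa) = c1 * log10(|psi_kPa| * S) + c2 * Db + c3

where S is the degree of saturation.  PR rises as soil dries or densifies,
which is the physical driver of the root "stop signal" studied here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SoilLayer",
    "HydraulicParams",
    "SoilProfile",
    "TEXTURE_CENTROIDS",
    "pedotransfer_saxton_rawls",
    "fit_van_genuchten",
    "retention_theta",
    "conductivity_K",
    "head_from_theta",
    "water_capacity",
    "penetration_resistance",
    "derive_hydraulics",
    "build_profile",
    "cultivate",
    "sandy_loam_profile",
    "silt_loam_profile",
]

# Matric head anchors for field capacity (-33 kPa) and permanent wilting
# point (-1500 kPa), in cm of water.
H_FIELD_CAPACITY = -337.0
H_WILTING_POINT = -15300.0

#: cm of water per kPa
CM_PER_KPA = 10.19716

#: USDA texture-triangle class centroids as (sand, silt, clay) mass fractions.
#: The built-in profiles name classes only; centroids stand in for
#: unavailable particle-size data and are overridable per layer.
TEXTURE_CENTROIDS: dict[str, tuple[float, float, float]] = {
    "sandy loam": (0.65, 0.25, 0.10),
    "clay loam": (0.32, 0.34, 0.34),
    "silt loam": (0.20, 0.65, 0.15),
    "silty clay": (0.07, 0.48, 0.45),
    "silty clay loam": (0.10, 0.57, 0.33),
}

# Whalley-type PR pedotransfer coefficients (c1, c2, c3) and the optional
# overburden gradient (kPa per cm depth).
PR_COEFFS_DEFAULT = (0.35, 0.93, 1.26)
PR_DEPTH_GRADIENT_DEFAULT = 0.0


class SoilDomainError(ValueError):
    """Raised when a soil quantity is outside its physical domain."""


class VanGenuchtenFitError(RuntimeError):
    """Raised when no retention curve with n > 1 fits the two anchors."""


@dataclass(frozen=True)
class HydraulicParams:
    """van Genuchten-Mualem parameter set for one soil layer.

    theta_r/theta_s are residual and saturated water contents (cm3 cm-3),
    alpha (cm-1) and n_shape (-) shape the retention curve, K_s is saturated
    conductivity (cm d-1).  theta_fc and theta_pwp are the water contents at
    -33 kPa and -1500 kPa used as fitting anchors.
    """

    theta_r: float
    theta_s: float
    alpha: float
    n_shape: float
    K_s: float
    theta_fc: float
    theta_pwp: float

    def __post_init__(self) -> None:
        if not (self.theta_r < self.theta_pwp < self.theta_fc < self.theta_s):
            raise SoilDomainError(
                "require theta_r < theta_pwp < theta_fc < theta_s, got "
                f"{self.theta_r}, {self.theta_pwp}, {self.theta_fc}, {self.theta_s}"
            )
        if self.alpha <= 0:
            raise SoilDomainError(f"alpha must be > 0, got {self.alpha}")
        if self.n_shape <= 1:
            raise SoilDomainError(f"n_shape must be > 1, got {self.n_shape}")
        if self.K_s <= 0:
            raise SoilDomainError(f"K_s must be > 0, got {self.K_s}")


@dataclass(frozen=True)
class SoilLayer:
    """One pedogenic horizon: depths (cm), texture, bulk density, OM."""

    top_depth: float
    bottom_depth: float
    texture_class: str
    bulk_density: float  # g cm-3
    organic_matter: float  # mass % of dry soil
    sand_fraction: float | None = None
    clay_fraction: float | None = None
    silt_fraction: float | None = None
    hydraulics: HydraulicParams | None = None

    def __post_init__(self) -> None:
        if self.top_depth < 0 or self.bottom_depth <= self.top_depth:
            raise SoilDomainError(
                f"bad layer depths [{self.top_depth}, {self.bottom_depth}]"
            )
        if not (0.8 <= self.bulk_density <= 2.0):
            raise SoilDomainError(
                f"bulk_density {self.bulk_density} outside [0.8, 2.0] g cm-3"
            )
        if self.sand_fraction is None:
            if self.texture_class not in TEXTURE_CENTROIDS:
                raise SoilDomainError(f"unknown texture class {self.texture_class!r}")
            sand, silt, clay = TEXTURE_CENTROIDS[self.texture_class]
            object.__setattr__(self, "sand_fraction", sand)
            object.__setattr__(self, "silt_fraction", silt)
            object.__setattr__(self, "clay_fraction", clay)
        total = self.sand_fraction + self.clay_fraction + self.silt_fraction
        if abs(total - 1.0) > 1e-9:
            raise SoilDomainError(f"texture fractions sum to {total}, expected 1")

    @property
    def thickness(self) -> float:
        return self.bottom_depth - self.top_depth


def pedotransfer_saxton_rawls(
    sand_fraction: float,
    clay_fraction: float,
    organic_matter: float,
    bulk_density: float | None = None,
) -> tuple[float, float, float, float]:
    """Saxton-Rawls (2006) regressions for the water characteristic.

    Parameters are sand and clay mass fractions (0-1) and organic matter in
    mass % (0-10).  Returns ``(theta_fc, theta_pwp, theta_s, K_s)`` with water
    contents in cm3 cm-3 and K_s in cm d-1.  When ``bulk_density`` is given,
    the published density adjustment replaces the regression porosity with
    1 - Db/2.65 and shifts field capacity accordingly.
    """
    if not 0.0 <= sand_fraction <= 1.0:
        raise SoilDomainError(f"sand_fraction {sand_fraction} outside [0, 1]")
    if not 0.0 <= clay_fraction <= 1.0:
        raise SoilDomainError(f"clay_fraction {clay_fraction} outside [0, 1]")
    if sand_fraction + clay_fraction > 1.0 + 1e-9:
        raise SoilDomainError("sand_fraction + clay_fraction exceed 1")
    if not 0.0 <= organic_matter <= 10.0:
        raise SoilDomainError(f"organic_matter {organic_matter} outside [0, 10] %")

    S, C, OM = sand_fraction, clay_fraction, organic_matter

    t1500 = (-0.024 * S + 0.487 * C + 0.006 * OM + 0.005 * S * OM
             - 0.013 * C * OM + 0.068 * S * C + 0.031)
    theta_pwp = t1500 + (0.14 * t1500 - 0.02)

    t33 = (-0.251 * S + 0.195 * C + 0.011 * OM + 0.006 * S * OM
           - 0.027 * C * OM + 0.452 * S * C + 0.299)
    theta_fc = t33 + (1.283 * t33 * t33 - 0.374 * t33 - 0.015)

    ts33 = (0.278 * S + 0.034 * C + 0.022 * OM - 0.018 * S * OM
            - 0.027 * C * OM - 0.584 * S * C + 0.078)
    theta_s33 = ts33 + (0.636 * ts33 - 0.107)

    theta_s = theta_fc + theta_s33 - 0.097 * S + 0.043

    if bulk_density is not None:
        theta_s_df = 1.0 - bulk_density / 2.65
        theta_fc = theta_fc - 0.2 * (theta_s - theta_s_df)
        theta_s = theta_s_df

    if not theta_pwp < theta_fc < theta_s:
        raise SoilDomainError(
            f"pedotransfer produced non-physical ordering for texture "
            f"sand={S}, clay={C}, OM={OM}: pwp={theta_pwp:.4f} fc={theta_fc:.4f} "
            f"sat={theta_s:.4f}"
        )

    # Saturated conductivity, mm/h in the source, converted to cm/d.
    B = (math.log(1500.0) - math.log(33.0)) / (math.log(theta_fc) - math.log(theta_pwp))
    lam = 1.0 / B
    K_s = 1930.0 * (theta_s - theta_fc) ** (3.0 - lam) * 2.4
    return theta_fc, theta_pwp, theta_s, K_s


def fit_van_genuchten(
    theta_r: float, theta_s: float, theta_fc: float, theta_pwp: float
) -> tuple[float, float]:
    """Solve (alpha, n) so the retention curve passes through both anchors.

    The curve theta(h) = theta_r + (theta_s - theta_r) / (1 + |alpha h|^n)^m,
    m = 1 - 1/n, is pinned to (H_FIELD_CAPACITY, theta_fc) and
    (H_WILTING_POINT, theta_pwp).  alpha is eliminated with the field-capacity
    anchor and n found by bracketed root solve.
    """
    if not (theta_r < theta_pwp < theta_fc < theta_s):
        raise SoilDomainError("require theta_r < theta_pwp < theta_fc < theta_s")

    se_fc = (theta_fc - theta_r) / (theta_s - theta_r)
    se_pwp = (theta_pwp - theta_r) / (theta_s - theta_r)
    h1, h2 = abs(H_FIELD_CAPACITY), abs(H_WILTING_POINT)

    def alpha_of(n: float) -> float:
        m = 1.0 - 1.0 / n
        return (se_fc ** (-1.0 / m) - 1.0) ** (1.0 / n) / h1

    def resid(n: float) -> float:
        m = 1.0 - 1.0 / n
        a = alpha_of(n)
        se2 = (1.0 + (a * h2) ** n) ** (-m)
        return se2 - se_pwp

    lo, hi = 1.02, 12.0
    flo, fhi = resid(lo), resid(hi)
    if flo * fhi > 0:
        raise VanGenuchtenFitError(
            f"no van Genuchten solution with n in ({lo}, {hi}) for anchors "
            f"fc={theta_fc}, pwp={theta_pwp}"
        )
    n = brentq(resid, lo, hi, xtol=1e-12, rtol=1e-14)
    return alpha_of(n), n


def retention_theta(h, params: HydraulicParams):
    """Volumetric water content at pressure head h (cm); h >= 0 saturates."""
    h = np.asarray(h, dtype=float)
    se = np.where(
        h >= 0.0,
        1.0,
        (1.0 + np.abs(params.alpha * np.minimum(h, 0.0)) ** params.n_shape)
        ** -(1.0 - 1.0 / params.n_shape),
    )
    out = params.theta_r + (params.theta_s - params.theta_r) * se
    return out if out.ndim else float(out)


def head_from_theta(theta, params: HydraulicParams):
    """Inverse retention curve; theta is clamped just inside (theta_r, theta_s)."""
    theta = np.asarray(theta, dtype=float)
    eps = 1e-12
    se = (np.clip(theta, params.theta_r + eps, params.theta_s - eps) - params.theta_r) / (
        params.theta_s - params.theta_r
    )
    m = 1.0 - 1.0 / params.n_shape
    h = -((se ** (-1.0 / m) - 1.0) ** (1.0 / params.n_shape)) / params.alpha
    h = np.where(theta >= params.theta_s, 0.0, h)
    return h if h.ndim else float(h)


def conductivity_K(h, params: HydraulicParams):
    """Unsaturated conductivity (cm d-1), van Genuchten-Mualem, tortuosity 0.5."""
    h = np.asarray(h, dtype=float)
    m = 1.0 - 1.0 / params.n_shape
    se = np.where(
        h >= 0.0,
        1.0,
        (1.0 + np.abs(params.alpha * np.minimum(h, 0.0)) ** params.n_shape) ** -m,
    )
    se = np.clip(se, 1e-12, 1.0)
    K = params.K_s * np.sqrt(se) * (1.0 - (1.0 - se ** (1.0 / m)) ** m) ** 2
    return K if K.ndim else float(K)


def water_capacity(h, params: HydraulicParams):
    """Specific moisture capacity C(h) = d(theta)/dh (cm-1), 0 when saturated."""
    h = np.asarray(h, dtype=float)
    n = params.n_shape
    m = 1.0 - 1.0 / n
    ah = np.abs(params.alpha * np.minimum(h, 0.0))
    C = (
        (params.theta_s - params.theta_r)
        * params.alpha * n * m
        * ah ** (n - 1.0)
        / (1.0 + ah ** n) ** (m + 1.0)
    )
    C = np.where(h >= 0.0, 0.0, C)
    return C if C.ndim else float(C)


def penetration_resistance(
    theta,
    params: HydraulicParams,
    bulk_density,
    depth=0.0,
    coeffs: tuple[float, float, float] = PR_COEFFS_DEFAULT,
    depth_gradient: float = PR_DEPTH_GRADIENT_DEFAULT,
):
    """Penetration resistance (kPa) from water status, Db and depth.

    Whalley-type pedotransfer on matric potential (kPa) times degree of
    saturation, plus an optional linear overburden term.  Strictly decreasing
    in theta and increasing in bulk density; at saturation the matric term
    vanishes and PR tends to the overburden contribution alone.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < params.theta_r - 1e-9) or np.any(theta > params.theta_s + 1e-9):
        raise SoilDomainError(
            "theta outside [theta_r, theta_s] in penetration_resistance"
        )
    c1, c2, c3 = coeffs
    h = np.asarray(head_from_theta(theta, params), dtype=float)
    psi_kpa = np.abs(h) / CM_PER_KPA
    sat = theta / params.theta_s
    arg = np.maximum(psi_kpa * sat, 1e-12)
    pr = 10.0 ** (c1 * np.log10(arg) + c2 * np.asarray(bulk_density) + c3)
    pr = pr + depth_gradient * np.asarray(depth)
    return pr if pr.ndim else float(pr)


# -- residual water content default: not derivable from Saxton-Rawls ---------
THETA_R_FRACTION_OF_PWP = 0.35
THETA_R_BOUNDS = (0.0249, 0.0911)


def derive_hydraulics(layer: SoilLayer) -> HydraulicParams:
    """Full hydraulic parameter set for a layer via pedotransfer + VG fit."""
    theta_fc, theta_pwp, theta_s, K_s = pedotransfer_saxton_rawls(
        layer.sand_fraction, layer.clay_fraction, layer.organic_matter,
        bulk_density=layer.bulk_density,
    )
    theta_r = THETA_R_FRACTION_OF_PWP * theta_pwp
    theta_r = min(max(theta_r, THETA_R_BOUNDS[0]), THETA_R_BOUNDS[1])
    theta_r = min(theta_r, 0.9 * theta_pwp)  # keep strictly below wilting point
    alpha, n = fit_van_genuchten(theta_r, theta_s, theta_fc, theta_pwp)
    return HydraulicParams(
        theta_r=theta_r, theta_s=theta_s, alpha=alpha, n_shape=n,
        K_s=K_s, theta_fc=theta_fc, theta_pwp=theta_pwp,
    )


@dataclass
class SoilProfile:
    """Layered profile discretized on a uniform node grid (z down, cm).

    Per-node parameter arrays mirror the layer each node center falls in,
    so solvers can operate on flat vectors without layer lookups.
    """

    layers: list[SoilLayer]
    grid_dz: float
    node_depths: np.ndarray = field(repr=False)
    layer_index: np.ndarray = field(repr=False)
    theta_r: np.ndarray = field(repr=False)
    theta_s: np.ndarray = field(repr=False)
    alpha: np.ndarray = field(repr=False)
    n_shape: np.ndarray = field(repr=False)
    K_s: np.ndarray = field(repr=False)
    theta_fc: np.ndarray = field(repr=False)
    theta_pwp: np.ndarray = field(repr=False)
    bulk_density: np.ndarray = field(repr=False)
    organic_matter: np.ndarray = field(repr=False)

    @property
    def total_depth(self) -> float:
        return self.layers[-1].bottom_depth

    @property
    def n_nodes(self) -> int:
        return self.node_depths.size

    def node_of_depth(self, z) -> np.ndarray:
        """Index of the grid cell containing depth z (clipped to the column)."""
        idx = np.floor(np.asarray(z, dtype=float) / self.grid_dz).astype(int)
        return np.clip(idx, 0, self.n_nodes - 1)

    def layer_params(self, i: int) -> HydraulicParams:
        return self.layers[self.layer_index[i]].hydraulics

    # vectorized closures over per-node parameter arrays -----------------

    def theta_of_head(self, h: np.ndarray) -> np.ndarray:
        m = 1.0 - 1.0 / self.n_shape
        se = np.where(
            h >= 0.0,
            1.0,
            (1.0 + np.abs(self.alpha * np.minimum(h, 0.0)) ** self.n_shape) ** -m,
        )
        return self.theta_r + (self.theta_s - self.theta_r) * se

    def head_of_theta(self, theta: np.ndarray) -> np.ndarray:
        eps = 1e-12
        se = (np.clip(theta, self.theta_r + eps, self.theta_s - eps) - self.theta_r) / (
            self.theta_s - self.theta_r
        )
        m = 1.0 - 1.0 / self.n_shape
        h = -((se ** (-1.0 / m) - 1.0) ** (1.0 / self.n_shape)) / self.alpha
        return np.where(theta >= self.theta_s, 0.0, h)

    def K_of_head(self, h: np.ndarray) -> np.ndarray:
        m = 1.0 - 1.0 / self.n_shape
        se = np.where(
            h >= 0.0,
            1.0,
            (1.0 + np.abs(self.alpha * np.minimum(h, 0.0)) ** self.n_shape) ** -m,
        )
        se = np.clip(se, 1e-12, 1.0)
        return self.K_s * np.sqrt(se) * (1.0 - (1.0 - se ** (1.0 / m)) ** m) ** 2

    def capacity_of_head(self, h: np.ndarray) -> np.ndarray:
        n = self.n_shape
        m = 1.0 - 1.0 / n
        ah = np.abs(self.alpha * np.minimum(h, 0.0))
        C = (
            (self.theta_s - self.theta_r) * self.alpha * n * m
            * ah ** (n - 1.0) / (1.0 + ah ** n) ** (m + 1.0)
        )
        return np.where(h >= 0.0, 0.0, C)

    def penetration_resistance_nodes(
        self,
        theta: np.ndarray,
        coeffs: tuple[float, float, float] = PR_COEFFS_DEFAULT,
        depth_gradient: float = PR_DEPTH_GRADIENT_DEFAULT,
    ) -> np.ndarray:
        c1, c2, c3 = coeffs
        theta = np.clip(theta, self.theta_r + 1e-12, self.theta_s)
        h = self.head_of_theta(theta)
        psi_kpa = np.abs(h) / CM_PER_KPA
        arg = np.maximum(psi_kpa * theta / self.theta_s, 1e-12)
        pr = 10.0 ** (c1 * np.log10(arg) + c2 * self.bulk_density + c3)
        return pr + depth_gradient * self.node_depths

    def to_frame(self):
        """Per-node derived soil table (for CSV export)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "depth_cm": self.node_depths,
                "theta_r": self.theta_r,
                "theta_s": self.theta_s,
                "alpha_per_cm": self.alpha,
                "n_shape": self.n_shape,
                "K_s_cm_d": self.K_s,
                "theta_fc": self.theta_fc,
                "theta_pwp": self.theta_pwp,
                "bulk_density": self.bulk_density,
                "organic_matter_pct": self.organic_matter,
            }
        )


def build_profile(layers: list[SoilLayer], grid_dz: float = 2.0) -> SoilProfile:
    """Discretize contiguous layers onto a node grid, deriving hydraulics."""
    if not layers:
        raise SoilDomainError("profile needs at least one layer")
    if abs(layers[0].top_depth) > 1e-9:
        raise SoilDomainError("first layer must start at the surface (0 cm)")
    for a, b in zip(layers, layers[1:]):
        if abs(a.bottom_depth - b.top_depth) > 1e-9:
            raise SoilDomainError(
                f"layers not contiguous at {a.bottom_depth} vs {b.top_depth} cm"
            )

    layers = [
        ly if ly.hydraulics is not None else replace(ly, hydraulics=derive_hydraulics(ly))
        for ly in layers
    ]
    total = layers[-1].bottom_depth
    n = int(round(total / grid_dz))
    node_depths = (np.arange(n) + 0.5) * grid_dz

    layer_index = np.empty(n, dtype=int)
    for i, z in enumerate(node_depths):
        for j, ly in enumerate(layers):
            if ly.top_depth - 1e-9 <= z < ly.bottom_depth + 1e-9:
                layer_index[i] = j
                break
        else:  # pragma: no cover - contiguity guarantees a hit
            raise SoilDomainError(f"node at {z} cm maps to no layer")

    def arr(attr):
        return np.array([getattr(layers[j].hydraulics, attr) for j in layer_index])

    return SoilProfile(
        layers=layers,
        grid_dz=grid_dz,
        node_depths=node_depths,
        layer_index=layer_index,
        theta_r=arr("theta_r"),
        theta_s=arr("theta_s"),
        alpha=arr("alpha"),
        n_shape=arr("n_shape"),
        K_s=arr("K_s"),
        theta_fc=arr("theta_fc"),
        theta_pwp=arr("theta_pwp"),
        bulk_density=np.array([layers[j].bulk_density for j in layer_index]),
        organic_matter=np.array([layers[j].organic_matter for j in layer_index]),
    )


def cultivate(profile: SoilProfile) -> SoilProfile:
    """Transform a native profile into its cultivated counterpart.

    The A horizon (first layer) loses half its thickness (erosion) and half
    its organic matter, and its bulk density rises by 10 % (compaction from
    tillage and traffic).  Deeper layers shift upward so the surface stays at
    0 cm; their properties are untouched.  Hydraulics are re-derived.
    """
    if not profile.layers:
        raise SoilDomainError("profile has no layers")
    a = profile.layers[0]
    new_thickness = a.thickness / 2.0
    new_a = SoilLayer(
        top_depth=0.0,
        bottom_depth=new_thickness,
        texture_class=a.texture_class,
        bulk_density=a.bulk_density * 1.10,
        organic_matter=a.organic_matter * 0.5,
        sand_fraction=a.sand_fraction,
        clay_fraction=a.clay_fraction,
        silt_fraction=a.silt_fraction,
    )
    shift = a.thickness - new_thickness
    new_layers = [new_a]
    for ly in profile.layers[1:]:
        new_layers.append(
            SoilLayer(
                top_depth=ly.top_depth - shift,
                bottom_depth=ly.bottom_depth - shift,
                texture_class=ly.texture_class,
                bulk_density=ly.bulk_density,
                organic_matter=ly.organic_matter,
                sand_fraction=ly.sand_fraction,
                clay_fraction=ly.clay_fraction,
                silt_fraction=ly.silt_fraction,
                hydraulics=ly.hydraulics,
            )
        )
    return build_profile(new_layers, grid_dz=profile.grid_dz)


def sandy_loam_profile(grid_dz: float = 2.0) -> SoilProfile:
    """Native sandy loam Inceptisol: sandy loam A to 73 cm, clay loam below,
    sandy loam again at 115-130 cm.  Db/OM are representative alluvial values."""
    return build_profile(
        [
            SoilLayer(0.0, 73.0, "sandy loam", bulk_density=1.45, organic_matter=2.0),
            SoilLayer(73.0, 115.0, "clay loam", bulk_density=1.50, organic_matter=0.5),
            SoilLayer(115.0, 130.0, "sandy loam", bulk_density=1.55, organic_matter=0.2),
        ],
        grid_dz=grid_dz,
    )


def silt_loam_profile(grid_dz: float = 2.0) -> SoilProfile:
    """Native silt loam Inceptisol: silt loam A to 22 cm, silty clay to 89 cm,
    silty clay loam to 160 cm."""
    return build_profile(
        [
            SoilLayer(0.0, 22.0, "silt loam", bulk_density=1.40, organic_matter=2.5),
            SoilLayer(22.0, 89.0, "silty clay", bulk_density=1.45, organic_matter=0.6),
            SoilLayer(89.0, 160.0, "silty clay loam", bulk_density=1.50, organic_matter=0.3),
        ],
        grid_dz=grid_dz,
    )
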