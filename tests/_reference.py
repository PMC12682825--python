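"""Independent fine-grid explicit Richards reference for solver validation."""

import numpy as np

from stopsignal.soils import HydraulicParams, conductivity_K, head_from_theta


def explicit_infiltration(
    params: HydraulicParams,
    theta0: float,
    q_top: float,
    total_depth: float,
    t_end: float,
    dz: float = 0.25,
    dt: float = 2.0e-5,
) -> np.ndarray:
    """Forward-Euler theta-form Richards solve on a fine uniform grid.

    Free drainage at the bottom, prescribed flux at the surface.  Returns
    the water-content profile at t_end (node centers at (i+0.5)*dz).
    """
    n = int(round(total_depth / dz))
    theta = np.full(n, theta0, dtype=float)
    steps = int(round(t_end / dt))
    for _ in range(steps):
        h = head_from_theta(theta, params)
        K = conductivity_K(h, params)
        Kf = 0.5 * (K[:-1] + K[1:])
        q = -Kf * ((h[1:] - h[:-1]) / dz - 1.0)
        q_bot = K[-1]
        div = np.empty(n)
        div[0] = (q_top - q[0]) / dz
        div[1:-1] = (q[:-1] - q[1:]) / dz
        div[-1] = (q[-1] - q_bot) / dz
        theta = np.clip(theta + dt * div, params.theta_r + 1e-9, params.theta_s)
    return theta
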