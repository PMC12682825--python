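"""The stop-signal growth-reduction function and the phenotype grid.

Roots attenuate elongation as soil mechanical impedance rises, ceasing
entirely at a ceiling impedance (~5 MPa).  The relative growth rate is

    y = 1 - (x / ceiling)^a        (0 for x >= ceiling)

where x is penetration resistance (kPa) and the exponent a sets penetration
ability: a = 1 is a linear ramp, a < 1 stops growth quickly (a sensitive
stop signal, i.e. a plastic root), a > 1 keeps growing into hard soil.
Axial and lateral root classes carry independent exponents; the default
level set (0.2, 0.4, 0.6, 0.8, 1, 1.5, 2) yields a 7 x 7 = 49 phenotype grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

__all__ = [
    "DEFAULT_LEVELS",
    "GROWTH_CEILING_KPA",
    "ImpedanceResponse",
    "Phenotype",
    "growth_reduction_factor",
    "phenotype_grid",
]

#: Impedance (kPa) at which root elongation ceases for every exponent.
GROWTH_CEILING_KPA = 5000.0

#: The seven default penetration-ability levels of the factorial design.
DEFAULT_LEVELS: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8, 1.0, 1.5, 2.0)


@dataclass(frozen=True)
class ImpedanceResponse:
    """Shape exponent and cessation ceiling of the stop-signal response."""

    exponent: float
    ceiling: float = GROWTH_CEILING_KPA

    def __post_init__(self) -> None:
        if self.exponent <= 0:
            raise ValueError(f"exponent must be > 0, got {self.exponent}")
        if self.ceiling <= 0:
            raise ValueError(f"ceiling must be > 0, got {self.ceiling}")


@dataclass(frozen=True)
class Phenotype:
    """An (axial, lateral) penetration-ability exponent pair."""

    a_axial: float
    a_lateral: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.a_axial <= 0 or self.a_lateral <= 0:
            raise ValueError("phenotype exponents must be > 0")
        if not self.label:
            object.__setattr__(self, "label", f"ax{self.a_axial:g}_lat{self.a_lateral:g}")


def growth_reduction_factor(x, response: ImpedanceResponse):
    """Relative root growth rate y in [0, 1] at impedance x (kPa).

    Clamped to 0 above the ceiling (the raw power law would go negative).
    Accepts scalars or arrays.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("impedance must be >= 0")
    ratio = np.minimum(x / response.ceiling, 1.0)
    y = 1.0 - ratio ** response.exponent
    y = np.clip(y, 0.0, 1.0)
    return y if y.ndim else float(y)


def phenotype_grid(levels: tuple[float, ...] = DEFAULT_LEVELS) -> list[Phenotype]:
    """Cartesian product of axial x lateral levels, a_axial-major order."""
    levels = tuple(levels)
    if not levels:
        raise ValueError("levels must be non-empty")
    if any(a <= 0 for a in levels):
        raise ValueError("levels must be strictly positive")
    if len(set(levels)) != len(levels):
        raise ValueError("levels must be unique")
    return [Phenotype(ax, lat) for ax, lat in product(levels, levels)]
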