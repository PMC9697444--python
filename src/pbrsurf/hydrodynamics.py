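"""Average shear rate at the bottom of an orbiting Petri dish.

An orbital shaker drives a rotating wave in the dish; the time-averaged
wall shear rate at the bottom scales as

    gamma_omega = r_eff * sqrt( rho * (2*pi*f)^3 / mu )

with f the orbital frequency, rho/mu the fluid density and dynamic
viscosity, and r_eff an effective orbital length lumping the geometry
(orbital and dish radii). The default r_eff = 0.0275 m reproduces the
operating map of the adhesion protocol this package supports
(50/100/150 rpm -> ~329/932/1712 s^-1 with water at room temperature).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .errors import InputError

DEFAULT_R_EFF_M = 0.0275
WATER_RHO = 1000.0  # kg m^-3
WATER_MU = 1e-3  # kg m^-1 s^-1


@dataclass(frozen=True)
class ShakerConfig:
    """Fluid properties and geometry of the orbital-shaker setup (SI units)."""

    rho: float = WATER_RHO
    mu: float = WATER_MU
    f: float = 100.0 / 60.0  # Hz
    r_eff: float = DEFAULT_R_EFF_M

    def __post_init__(self) -> None:
        for label, v in (("rho", self.rho), ("mu", self.mu), ("f", self.f), ("r_eff", self.r_eff)):
            if v <= 0.0:
                raise InputError(f"ShakerConfig.{label} must be > 0, got {v}")


def rpm_to_hz(rpm: float) -> float:
    """Orbital shaking rate, revolutions per minute -> Hz."""
    if rpm < 0:
        raise InputError(f"rpm must be >= 0, got {rpm}")
    return rpm / 60.0


def orbital_shear_rate(cfg: ShakerConfig) -> float:
    """gamma_omega = r_eff * sqrt(rho*(2*pi*f)^3 / mu), in s^-1."""
    return cfg.r_eff * math.sqrt(cfg.rho * (2.0 * math.pi * cfg.f) ** 3 / cfg.mu)


def shear_rate_table(
    rpms: Iterable[float],
    rho: float = WATER_RHO,
    mu: float = WATER_MU,
    r_eff: float = DEFAULT_R_EFF_M,
) -> pd.DataFrame:
    """Shear rates for a list of shaking rates; columns (rpm, gamma_omega)."""
    rows = [
        {"rpm": rpm, "gamma_omega": orbital_shear_rate(ShakerConfig(rho, mu, rpm_to_hz(rpm), r_eff))}
        for rpm in rpms
    ]
    return pd.DataFrame(rows)
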