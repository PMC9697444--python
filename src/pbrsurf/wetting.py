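"""Wettability metrics and biocompatibility classification.

Two classical screening metrics complement the acid-base decomposition:

* water adhesion tension, tau0 = gamma_w * cos(theta_w), with Vogler's
  empirical hydrophilicity threshold tau0 > 30 mJ m^-2;
* Zisman critical surface tension gamma_c, the liquid surface tension at
  which the least-squares line through (gamma_L, cos theta) reaches
  cos theta = 1 (complete wetting). Baier's biocompatibility curve places
  minimal biological adhesion in a low-gamma_c band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .errors import InputError, SolverError
from .liquids import ProbeLiquid
from .surface_energy import AngleSet

VOGLER_THRESHOLD = 30.0  # mJ m^-2
BAIER_ZONE = (20.0, 30.0)  # mJ m^-2, minimal-fouling band (closed interval)


@dataclass(frozen=True)
class WettingProfile:
    tau0: float
    gamma_c: float
    gamma_c_r2: float
    vogler_class: str
    baier_in_minimum: bool


def water_adhesion_tension(theta_w: float, water: ProbeLiquid) -> float:
    """tau0 = gamma_w * cos(theta_w), mJ m^-2; theta_w in degrees."""
    if not (0.0 <= theta_w < 180.0):
        raise InputError(f"theta_w = {theta_w} outside [0, 180)")
    return water.gamma_total * float(np.cos(np.radians(theta_w)))


def critical_surface_tension(
    angles: AngleSet, liquids: Mapping[str, ProbeLiquid]
) -> tuple[float, float]:
    """Zisman extrapolation of cos(theta) vs gamma_L to cos(theta) = 1.

    Fits ordinary least squares over all supplied liquids (all three by
    default, even when the points are non-monotonic) and returns
    (gamma_c, r^2). Low r^2 flags a fit the caller should not trust.
    """
    gamma_l = []
    cos_t = []
    for name, theta in (
        ("water", angles.theta_w),
        ("formamide", angles.theta_f),
        ("diiodomethane", angles.theta_d),
    ):
        if name in liquids:
            gamma_l.append(liquids[name].gamma_total)
            cos_t.append(np.cos(np.radians(theta)))
    if len(set(gamma_l)) < 2:
        raise InputError("Zisman fit needs >= 2 liquids with distinct surface tensions")
    fit = stats.linregress(gamma_l, cos_t)
    if fit.slope == 0.0:
        raise SolverError("indeterminate critical tension: zero Zisman slope")
    gamma_c = (1.0 - fit.intercept) / fit.slope
    return float(gamma_c), float(fit.rvalue**2)


def classify_vogler(tau0: float, threshold: float = VOGLER_THRESHOLD) -> str:
    """Vogler water-wettability class: strictly above the threshold is
    ``"hydrophilic"``, otherwise ``"hydrophobic"``."""
    return "hydrophilic" if tau0 > threshold else "hydrophobic"


def baier_zone(gamma_c: float, zone: tuple[float, float] = BAIER_ZONE) -> bool:
    """True iff gamma_c lies inside the minimal-fouling band (closed)."""
    lo, hi = zone
    return lo <= gamma_c <= hi


def wetting_profile(
    angles: AngleSet,
    liquids: Mapping[str, ProbeLiquid],
    vogler_threshold: float = VOGLER_THRESHOLD,
    baier_interval: tuple[float, float] = BAIER_ZONE,
) -> WettingProfile:
    """Assemble the full wettability profile for one surface."""
    tau0 = water_adhesion_tension(angles.theta_w, liquids["water"])
    gamma_c, r2 = critical_surface_tension(angles, liquids)
    return WettingProfile(
        tau0=tau0,
        gamma_c=gamma_c,
        gamma_c_r2=r2,
        vogler_class=classify_vogler(tau0, vogler_threshold),
        baier_in_minimum=baier_zone(gamma_c, baier_interval),
    )
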