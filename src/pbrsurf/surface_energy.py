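"""Three-liquid acid-base surface-energy inversion.

A sessile drop of liquid *i* on a solid *s* obeys the Young-Dupre relation

    gamma_Li * (1 + cos theta_i)
        = 2 * ( sqrt(gamma_s_LW * gamma_Li_LW)
              + sqrt(gamma_s_plus * gamma_Li_minus)
              + sqrt(gamma_s_minus * gamma_Li_plus) )

Measuring theta for an apolar liquid (diiodomethane) and two polar
liquids (water, formamide) gives three equations in the three solid
unknowns: the apolar equation yields gamma_s_LW in closed form, and the
two polar equations become a 2x2 linear system in a = sqrt(gamma_s_plus)
and b = sqrt(gamma_s_minus).

For strongly monopolar solids the linear solve can return a negative a
(or b). This module carries the *magnitudes* |a|, |b| into
gamma_plus = a^2, gamma_minus = b^2, gamma_AB = 2|a||b| and all cohesion
cross terms, and records which roots solved negative in
``root_sign_flags`` so callers can audit. This convention is what
reproduces published total surface energies for monopolar polymers.

The free energy of cohesion of the solid immersed in water,
dG_coh = -2*gamma_sw, classifies the surface: positive means hydrophilic
(the surface prefers water over itself), negative hydrophobic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import InputError, SolverError
from .liquids import ProbeLiquid

POLAR_LIQUIDS = ("water", "formamide")
APOLAR_LIQUID = "diiodomethane"


@dataclass(frozen=True)
class AngleSet:
    """Mean contact angles (degrees) of the three probe liquids on one surface.

    Replicate standard deviations are optional and carried for reporting;
    the inversion always runs on the means.
    """

    surface_id: str
    theta_w: float
    theta_f: float
    theta_d: float
    sd_w: float | None = None
    sd_f: float | None = None
    sd_d: float | None = None
    n_replicates: int = 1

    def __post_init__(self) -> None:
        for label, theta in (("theta_w", self.theta_w), ("theta_f", self.theta_f), ("theta_d", self.theta_d)):
            if not (0.0 <= theta < 180.0):
                raise InputError(f"{self.surface_id}: {label} = {theta} outside [0, 180)")
        for label, sd in (("sd_w", self.sd_w), ("sd_f", self.sd_f), ("sd_d", self.sd_d)):
            if sd is not None and sd < 0.0:
                raise InputError(f"{self.surface_id}: {label} = {sd} negative")


@dataclass(frozen=True)
class SurfaceEnergyResult:
    """Solved acid-base components of a solid surface, mJ m^-2."""

    gamma_lw: float
    gamma_plus: float
    gamma_minus: float
    gamma_ab: float
    gamma_s: float
    delta_g_coh: float
    root_sign_flags: tuple[bool, bool] = field(default=(False, False))

    def __post_init__(self) -> None:
        if min(self.gamma_lw, self.gamma_plus, self.gamma_minus) < 0.0:
            raise SolverError("surface-energy components must be non-negative")


def gamma_lw_from_apolar(theta_d: float, apolar: ProbeLiquid) -> float:
    """Lifshitz-van der Waals component from the apolar-liquid contact angle.

    With gamma_plus = gamma_minus = 0 the Young-Dupre relation collapses to
    gamma_s_LW = gamma_D * (1 + cos theta_D)^2 / 4.
    """
    if not apolar.is_apolar:
        raise InputError(f"{apolar.name} is not apolar (gamma_plus/minus nonzero)")
    return apolar.gamma_lw * (1.0 + math.cos(math.radians(theta_d))) ** 2 / 4.0


def _polar_system(
    gamma_lw: float, angles: Mapping[str, float], liquids: Mapping[str, ProbeLiquid]
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the 2x2 linear system in (a, b) from the polar equations."""
    rows, rhs = [], []
    for name in POLAR_LIQUIDS:
        liq = liquids[name]
        cos_t = math.cos(math.radians(angles[name]))
        rows.append([2.0 * math.sqrt(liq.gamma_minus), 2.0 * math.sqrt(liq.gamma_plus)])
        rhs.append(liq.gamma_total * (1.0 + cos_t) - 2.0 * math.sqrt(gamma_lw * liq.gamma_lw))
    return np.asarray(rows), np.asarray(rhs)


def solve_components(
    angles: AngleSet, liquids: Mapping[str, ProbeLiquid], water: ProbeLiquid | None = None
) -> SurfaceEnergyResult:
    """Invert the three Young-Dupre equations for one surface.

    Parameters
    ----------
    angles
        Mean contact-angle triple for the surface.
    liquids
        Registry containing at least water, formamide and diiodomethane.

    Returns
    -------
    SurfaceEnergyResult
        Components under the magnitude convention, with the cohesion free
        energy in water already attached.
    """
    for name in (*POLAR_LIQUIDS, APOLAR_LIQUID):
        if name not in liquids:
            raise InputError(f"liquid set lacks {name!r}")
    gamma_lw = gamma_lw_from_apolar(angles.theta_d, liquids[APOLAR_LIQUID])
    mat, rhs = _polar_system(
        gamma_lw, {"water": angles.theta_w, "formamide": angles.theta_f}, liquids
    )
    det = float(np.linalg.det(mat))
    # rows are 2[sqrt(gamma_minus), sqrt(gamma_plus)] per liquid; a vanishing
    # determinant means the two polar liquids have proportional acid/base
    # character and cannot separate a from b
    if abs(det) < 1e-10 * float(np.abs(mat).max() or 1.0) ** 2:
        raise SolverError(
            "polar liquid pair is degenerate (singular 2x2 system): rows "
            f"{POLAR_LIQUIDS[0]}={mat[0].tolist()}, {POLAR_LIQUIDS[1]}={mat[1].tolist()}"
        )
    a, b = np.linalg.solve(mat, rhs)
    flags = (bool(a < 0.0), bool(b < 0.0))
    a, b = abs(float(a)), abs(float(b))
    gamma_ab = 2.0 * a * b
    result = SurfaceEnergyResult(
        gamma_lw=gamma_lw,
        gamma_plus=a * a,
        gamma_minus=b * b,
        gamma_ab=gamma_ab,
        gamma_s=gamma_lw + gamma_ab,
        delta_g_coh=float("nan"),
        root_sign_flags=flags,
    )
    water = water if water is not None else liquids["water"]
    dg = delta_g_cohesion(result, water)
    object.__setattr__(result, "delta_g_coh", dg)
    return result


def delta_g_cohesion(result: SurfaceEnergyResult, water: ProbeLiquid) -> float:
    """Free energy of cohesion of the surface immersed in water, mJ m^-2.

    dG_coh = -2*gamma_sw, where the solid-water interfacial tension is

        gamma_sw = (sqrt(gamma_s_LW) - sqrt(gamma_w_LW))^2
                 + 2*( sqrt(gamma_s_plus*gamma_s_minus)
                     + sqrt(gamma_w_plus*gamma_w_minus)
                     - sqrt(gamma_s_plus*gamma_w_minus)
                     - sqrt(gamma_s_minus*gamma_w_plus) )

    Positive dG_coh marks a hydrophilic surface, negative a hydrophobic one.
    """
    a = math.sqrt(result.gamma_plus)
    b = math.sqrt(result.gamma_minus)
    gamma_sw = (math.sqrt(result.gamma_lw) - math.sqrt(water.gamma_lw)) ** 2 + 2.0 * (
        a * b
        + math.sqrt(water.gamma_plus * water.gamma_minus)
        - a * math.sqrt(water.gamma_minus)
        - b * math.sqrt(water.gamma_plus)
    )
    return -2.0 * gamma_sw


def forward_angles(
    components: SurfaceEnergyResult | tuple[float, float, float],
    liquids: Mapping[str, ProbeLiquid],
    surface_id: str = "forward",
) -> AngleSet:
    """Evaluate the forward Young-Dupre map: components -> angle triple.

    Accepts either a solved result or a raw (gamma_lw, gamma_plus,
    gamma_minus) triple with every entry >= 0. A component set whose
    work of adhesion exceeds 2*gamma_L spreads the liquid completely;
    the angle is then 0 (superwetting), which loses information for the
    inverse problem. cos theta below -1 cannot occur for non-negative
    components and raises defensively.
    """
    if isinstance(components, SurfaceEnergyResult):
        glw, gp, gm = components.gamma_lw, components.gamma_plus, components.gamma_minus
    else:
        glw, gp, gm = components
    if min(glw, gp, gm) < 0.0:
        raise InputError("components must be non-negative")
    thetas = {}
    for name in ("water", "formamide", "diiodomethane"):
        liq = liquids[name]
        work = 2.0 * (
            math.sqrt(glw * liq.gamma_lw)
            + math.sqrt(gp * liq.gamma_minus)
            + math.sqrt(gm * liq.gamma_plus)
        )
        cos_t = work / liq.gamma_total - 1.0
        if cos_t < -1.0:
            raise SolverError(
                f"unphysical component set: cos(theta_{name}) = {cos_t:.4f}"
            )
        thetas[name] = math.degrees(math.acos(min(cos_t, 1.0)))
    return AngleSet(
        surface_id=surface_id,
        theta_w=thetas["water"],
        theta_f=thetas["formamide"],
        theta_d=thetas["diiodomethane"],
    )
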