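"""Surface zeta potential from displacement-resolved tracer measurements.

Near a charged wall the apparent (tracer-reported) zeta potential is
dominated by electro-osmotic flow; far from the wall by the tracer's own
electrophoretic mobility. Measuring the apparent zeta at several
displacements from the wall (typically 125-625 um) and once in the far
field (1000 um, giving the tracer value zeta_m), the wall potential is
recovered by extrapolating the near-wall points linearly to zero
displacement:

    zeta_s = -intercept + zeta_m
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InputError

STANDARD_DISPLACEMENTS_UM = (125.0, 250.0, 375.0, 500.0, 625.0)
FAR_FIELD_UM = 1000.0


@dataclass(frozen=True)
class ZetaProfile:
    """Apparent zeta (mV) vs displacement from the wall (um) for one surface.

    ``zeta_far`` is the tracer zeta recorded in the far field (zeta_m); it is
    *not* part of the regression.
    """

    surface_id: str
    displacements: tuple[float, ...]
    apparent_zeta: tuple[float, ...]
    zeta_far: float
    tracer: str = "standard"
    nacl_mM: float = 0.0

    def __post_init__(self) -> None:
        d = np.asarray(self.displacements, dtype=float)
        z = np.asarray(self.apparent_zeta, dtype=float)
        if d.size < 2 or z.size != d.size:
            raise InputError(
                f"{self.surface_id}: need >= 2 (displacement, zeta) pairs of equal length"
            )
        if not (np.all(d > 0) and np.all(np.diff(d) > 0)):
            raise InputError(f"{self.surface_id}: displacements must be positive and strictly increasing")


def surface_zeta(profile: ZetaProfile) -> tuple[float, float, float]:
    """Extrapolate the near-wall linear fit to the surface.

    Returns ``(zeta_s, intercept, slope)`` with zeta_s and intercept in mV
    and slope in mV/um. OLS over the profile's points; the far-field tracer
    value enters only through zeta_s = -intercept + zeta_m.
    """
    fit = stats.linregress(profile.displacements, profile.apparent_zeta)
    intercept = float(fit.intercept)
    return -intercept + profile.zeta_far, intercept, float(fit.slope)


def profile_from_points(
    surface_id: str,
    displacements_um: Sequence[float],
    zeta_mV: Sequence[float],
    tracer: str = "standard",
    nacl_mM: float = 0.0,
    far_field_um: float = FAR_FIELD_UM,
) -> ZetaProfile:
    """Build a profile from raw rows, splitting off the far-field point.

    Rows at ``far_field_um`` (or beyond) are averaged into zeta_m; the rest
    form the near-wall regression set.
    """
    d = np.asarray(displacements_um, dtype=float)
    z = np.asarray(zeta_mV, dtype=float)
    far = d >= far_field_um
    if not far.any():
        raise InputError(f"{surface_id}: no far-field measurement at >= {far_field_um} um")
    order = np.argsort(d[~far])
    return ZetaProfile(
        surface_id=surface_id,
        displacements=tuple(d[~far][order]),
        apparent_zeta=tuple(z[~far][order]),
        zeta_far=float(z[far].mean()),
        tracer=tracer,
        nacl_mM=nacl_mM,
    )
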