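"""Probe-liquid surface-tension parameters.

The acid-base (van Oss-Chaudhury-Good) decomposition writes a liquid's
surface tension as

    gamma_total = gamma_LW + 2*sqrt(gamma_plus * gamma_minus)

with a Lifshitz-van der Waals (dispersive) component and Lewis
electron-acceptor / electron-donor parameters. The three-liquid scheme
used throughout this package probes a solid with two polar liquids
(water, formamide) and one apolar liquid (diiodomethane). The default
parameter set below is the van Oss reference set at 20 degrees C, in
mJ m^-2 (numerically identical to mN m^-1).
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping

from .errors import InputError

#: Allowed defect in the internal-consistency identity
#: gamma_total = gamma_lw + 2*sqrt(gamma_plus*gamma_minus), mJ m^-2.
CONSISTENCY_TOL = 0.1


@dataclass(frozen=True)
class ProbeLiquid:
    """Surface-tension parameters of one probe liquid, all in mJ m^-2."""

    name: str
    gamma_total: float
    gamma_lw: float
    gamma_plus: float
    gamma_minus: float

    def __post_init__(self) -> None:
        if not (self.gamma_total >= self.gamma_lw >= 0.0):
            raise InputError(
                f"{self.name}: need gamma_total >= gamma_lw >= 0, got "
                f"{self.gamma_total} / {self.gamma_lw}"
            )
        if self.gamma_plus < 0.0 or self.gamma_minus < 0.0:
            raise InputError(f"{self.name}: acid/base parameters must be >= 0")
        ab = 2.0 * (self.gamma_plus * self.gamma_minus) ** 0.5
        if abs(self.gamma_total - self.gamma_lw - ab) > CONSISTENCY_TOL:
            raise InputError(
                f"{self.name}: inconsistent parameters, gamma_lw + "
                f"2*sqrt(gamma_plus*gamma_minus) = {self.gamma_lw + ab:.3f} "
                f"!= gamma_total = {self.gamma_total}"
            )

    @property
    def is_apolar(self) -> bool:
        return self.gamma_plus == 0.0 and self.gamma_minus == 0.0


def default_liquid_set() -> Mapping[str, ProbeLiquid]:
    """Return the default water / formamide / diiodomethane registry.

    The mapping is read-only; overrides go through :func:`liquids_from_config`.
    """
    return MappingProxyType(
        {
            "water": ProbeLiquid("water", 72.8, 21.8, 25.5, 25.5),
            "formamide": ProbeLiquid("formamide", 58.0, 39.0, 2.28, 39.6),
            "diiodomethane": ProbeLiquid("diiodomethane", 50.8, 50.8, 0.0, 0.0),
        }
    )


def liquids_from_config(section: Mapping[str, Mapping[str, float]] | None) -> Mapping[str, ProbeLiquid]:
    """Merge a ``liquids:`` config section over the default registry.

    Each entry supplies ``gamma_total``, ``gamma_lw``, ``gamma_plus``,
    ``gamma_minus`` for a liquid; unnamed liquids keep their defaults.
    Values are validated through :class:`ProbeLiquid`.
    """
    merged = dict(default_liquid_set())
    if section:
        for name, params in section.items():
            try:
                merged[name] = ProbeLiquid(
                    name,
                    float(params["gamma_total"]),
                    float(params["gamma_lw"]),
                    float(params["gamma_plus"]),
                    float(params["gamma_minus"]),
                )
            except KeyError as exc:
                raise InputError(f"liquid {name!r}: missing parameter {exc}") from None
    return MappingProxyType(merged)
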