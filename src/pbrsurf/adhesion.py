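"""Control-normalized EPS adhesion and Fisher-LSD grouping.

Adhered exopolymeric-substance (EPS) mass per unit area is expressed
relative to a control surface (borosilicate glass in the reference
protocol, ~3.0 ug cm^-2 of BSA):

    % adhered EPS = 100 * (m_surface / A_surface) / (m_control / A_control)

Treatments (material x roughness combinations) are compared by one-way
ANOVA followed by Fisher's least-significant-difference (LSD) post-hoc
test at the 95% level, summarized as a compact letter display: two
treatments share a letter iff their mean difference is below the LSD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import InputError


@dataclass(frozen=True)
class AdhesionRecord:
    """One replicate measurement of adhered EPS mass on one coupon."""

    surface_id: str
    material: str
    ra: float  # um
    eps_type: str  # "BSA" | "PST"
    mass_adhered: float  # ug
    area: float  # cm^2
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.mass_adhered < 0 or self.area <= 0 or self.ra < 0:
            raise InputError(
                f"{self.surface_id}: need mass >= 0, area > 0, Ra >= 0 "
                f"(got {self.mass_adhered}, {self.area}, {self.ra})"
            )


@dataclass(frozen=True)
class GroupingResult:
    """One-way ANOVA + Fisher LSD summary for a set of treatments."""

    letters: dict[str, str]
    f_statistic: float
    p_value: float
    lsd: float
    degenerate: bool = False  # zero within-group variance


def relative_adhesion(record: AdhesionRecord, control_mass: float, control_area: float) -> float:
    """Adhesion of one coupon as a percentage of the control surface density."""
    if control_area <= 0:
        raise InputError("control area must be > 0")
    control_density = control_mass / control_area
    if control_density <= 0:
        raise InputError("control surface density must be > 0")
    return 100.0 * (record.mass_adhered / record.area) / control_density


def _one_way_anova(groups: Sequence[np.ndarray]) -> tuple[float, float, float, int]:
    """F, p, MSE, df_error from direct sums of squares."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_e = all_vals.size - len(groups)
    mse = ss_within / df_e
    if mse == 0.0:
        return math.inf, 0.0, 0.0, df_e
    f = (ss_between / df_b) / mse
    p = float(stats.f.sf(f, df_b, df_e))
    return float(f), p, float(mse), df_e


def _compact_letters(names: Sequence[str], nonsig: Mapping[tuple[str, str], bool]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``nonsig[(a, b)]`` is True when treatments a and b are NOT significantly
    different. Starting from one column holding every treatment, each
    significant pair splits every column containing both; columns that end
    up as subsets of another are absorbed. Letter sets may overlap (standard
    CLD semantics) but never contradict a pairwise verdict. Treatments are
    processed in input order, so the output is deterministic.
    """
    columns: list[set[str]] = [set(names)]
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if nonsig[tuple(sorted((a, b)))]:
                continue
            split: list[set[str]] = []
            for col in columns:
                if a in col and b in col:
                    split.append(col - {a})
                    split.append(col - {b})
                else:
                    split.append(col)
            # absorb: drop empties, strict subsets and duplicates (order-stable)
            columns = []
            for col in split:
                if col and not any(col < other for other in split) and col not in columns:
                    columns.append(col)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {n: "" for n in names}
    for letter, col in zip(alphabet, columns):
        for n in names:
            if n in col:
                letters[n] += letter
    return letters


def anova_lsd(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> GroupingResult:
    """One-way ANOVA with Fisher's LSD compact letter display.

    For balanced designs LSD = t(1 - alpha/2, df_error) * sqrt(2*MSE/n);
    unbalanced designs use the harmonic mean of the group sizes for n.
    With zero within-group variance the F test is degenerate; letters then
    fall back to exact-tie comparison and the result is flagged.
    """
    if len(groups) < 2:
        raise InputError("need >= 2 treatments")
    names = list(groups)
    arrays = []
    for name in names:
        arr = np.asarray(groups[name], dtype=float)
        if arr.size < 2:
            raise InputError(f"treatment {name!r} has < 2 replicates")
        arrays.append(arr)
    f, p, mse, df_e = _one_way_anova(arrays)
    if mse == 0.0:
        means = {n: float(a.mean()) for n, a in zip(names, arrays)}
        nonsig = {
            tuple(sorted((a, b))): means[a] == means[b]
            for i, a in enumerate(names)
            for b in names[i:]
        }
        return GroupingResult(
            letters=_compact_letters(names, nonsig),
            f_statistic=f,
            p_value=float("nan"),
            lsd=0.0,
            degenerate=True,
        )
    n_harm = len(arrays) / sum(1.0 / a.size for a in arrays)
    t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, df_e))
    lsd = t_crit * math.sqrt(2.0 * mse / n_harm)
    means = {n: float(a.mean()) for n, a in zip(names, arrays)}
    nonsig = {
        tuple(sorted((a, b))): abs(means[a] - means[b]) < lsd
        for i, a in enumerate(names)
        for b in names[i:]
    }
    return GroupingResult(
        letters=_compact_letters(names, nonsig),
        f_statistic=f,
        p_value=p,
        lsd=lsd,
    )
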