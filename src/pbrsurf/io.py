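"""CSV readers/writers, run configuration and the characterization pipeline.

All tables are plain UTF-8 comma-separated files with a header row and
decimal points. Supported inputs:

* contact angles, long form (surface_id, liquid, angle_deg[, replicate])
  or wide form (surface_id, theta_w, theta_f, theta_d[, sd_w, sd_f, sd_d]);
* zeta profiles (surface_id, tracer, nacl_mM, displacement_um, zeta_mV),
  far field marked by displacement_um >= 1000 or an is_far_field column;
* adhesion replicates (surface_id, material, ra_um, eps_type, mass_ug,
  area_cm2, replicate).

:func:`run_characterization` chains the stages into the per-surface
report: solved energy components, cohesion free energy, water adhesion
tension, critical surface tension and the Vogler/Baier labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .adhesion import AdhesionRecord
from .errors import InputError
from .liquids import ProbeLiquid, liquids_from_config
from .surface_energy import AngleSet, solve_components
from .wetting import BAIER_ZONE, VOGLER_THRESHOLD, wetting_profile
from .zeta import FAR_FIELD_UM, ZetaProfile, profile_from_points, surface_zeta

log = logging.getLogger("pbrsurf")

LIQUID_COLUMN = {"water": "theta_w", "formamide": "theta_f", "diiodomethane": "theta_d"}

#: Report columns, mirroring the characterization-table layout of the
#: wettability literature (Ra first, then angles, then derived energies).
REPORT_COLUMNS = [
    "surface_id",
    "theta_w",
    "theta_f",
    "theta_d",
    "gamma_lw",
    "gamma_plus",
    "gamma_minus",
    "gamma_ab",
    "gamma_s",
    "delta_g_coh",
    "tau0",
    "gamma_c",
    "gamma_c_r2",
    "vogler_class",
    "baier_in_minimum",
    "root_sign_plus",
    "root_sign_minus",
]


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs beyond the input tables."""

    liquids: Mapping[str, ProbeLiquid] = field(default_factory=lambda: liquids_from_config(None))
    vogler_threshold: float = VOGLER_THRESHOLD
    baier_interval: tuple[float, float] = BAIER_ZONE
    lsd_alpha: float = 0.05
    control_surface_id: str = "GS"
    seed: int = 0


def run_config_from_yaml(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML file; absent keys keep their defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    baier = raw.get("baier_interval", BAIER_ZONE)
    return RunConfig(
        liquids=liquids_from_config(raw.get("liquids")),
        vogler_threshold=float(raw.get("vogler_threshold", VOGLER_THRESHOLD)),
        baier_interval=(float(baier[0]), float(baier[1])),
        lsd_alpha=float(raw.get("lsd_alpha", 0.05)),
        control_surface_id=str(raw.get("control_surface_id", "GS")),
        seed=int(raw.get("seed", 0)),
    )


def _require_columns(df: pd.DataFrame, required: set[str], path: str | Path) -> None:
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing column(s) {sorted(missing)}")


def read_angle_table(path: str | Path) -> list[AngleSet]:
    """Read a contact-angle CSV (long or wide form) into mean AngleSets.

    Long-form replicate rows are aggregated to mean +/- SD per surface and
    liquid. Malformed rows raise :class:`~pbrsurf.errors.InputError` naming
    the offending row.
    """
    df = pd.read_csv(path)
    if "liquid" in df.columns:
        return _angles_from_long(df, path)
    return _angles_from_wide(df, path)


def _check_angle(value: float, row_label: str, path: str | Path) -> float:
    try:
        angle = float(value)
    except (TypeError, ValueError):
        raise InputError(f"{path}: non-numeric angle in {row_label}") from None
    if not (0.0 <= angle < 180.0):
        raise InputError(f"{path}: angle {angle} outside [0, 180) in {row_label}")
    return angle


def _angles_from_long(df: pd.DataFrame, path: str | Path) -> list[AngleSet]:
    _require_columns(df, {"surface_id", "liquid", "angle_deg"}, path)
    for idx, row in df.iterrows():
        _check_angle(row["angle_deg"], f"row {idx + 2}", path)  # +2: header + 1-based
        if row["liquid"] not in LIQUID_COLUMN:
            raise InputError(f"{path}: unknown liquid {row['liquid']!r} in row {idx + 2}")
    out = []
    for sid, grp in df.groupby("surface_id", sort=False):
        stats = {}
        for liquid, col in LIQUID_COLUMN.items():
            vals = grp.loc[grp["liquid"] == liquid, "angle_deg"]
            if vals.empty:
                raise InputError(f"{path}: surface {sid!r} lacks {liquid} angles")
            stats[col] = vals.mean()
            stats["sd_" + col[-1]] = vals.std(ddof=1) if len(vals) > 1 else None
            stats.setdefault("n", len(vals))
        out.append(
            AngleSet(
                surface_id=str(sid),
                theta_w=stats["theta_w"],
                theta_f=stats["theta_f"],
                theta_d=stats["theta_d"],
                sd_w=stats["sd_w"],
                sd_f=stats["sd_f"],
                sd_d=stats["sd_d"],
                n_replicates=stats["n"],
            )
        )
    return out


def _angles_from_wide(df: pd.DataFrame, path: str | Path) -> list[AngleSet]:
    _require_columns(df, {"surface_id", "theta_w", "theta_f", "theta_d"}, path)
    out = []
    for idx, row in df.iterrows():
        angles = {
            col: _check_angle(row[col], f"row {idx + 2} ({row['surface_id']})", path)
            for col in ("theta_w", "theta_f", "theta_d")
        }
        sds = {
            f"sd_{c[-1]}": (float(row[f"sd_{c[-1]}"]) if f"sd_{c[-1]}" in df.columns and pd.notna(row.get(f"sd_{c[-1]}")) else None)
            for c in ("theta_w", "theta_f", "theta_d")
        }
        out.append(
            AngleSet(
                surface_id=str(row["surface_id"]),
                **angles,
                **sds,
                n_replicates=int(row["n_replicates"]) if "n_replicates" in df.columns else 1,
            )
        )
    return out


def read_zeta_table(path: str | Path) -> list[ZetaProfile]:
    """Read displacement-resolved zeta CSV into per-surface profiles."""
    df = pd.read_csv(path)
    _require_columns(df, {"surface_id", "displacement_um", "zeta_mV"}, path)
    profiles = []
    group_cols = ["surface_id"] + [c for c in ("tracer", "nacl_mM") if c in df.columns]
    for key, grp in df.groupby(group_cols, sort=False):
        key = key if isinstance(key, tuple) else (key,)
        meta = dict(zip(group_cols, key))
        if "is_far_field" in grp.columns:
            far = grp["is_far_field"].astype(bool)
            near = grp[~far].sort_values("displacement_um")
            profiles.append(
                ZetaProfile(
                    surface_id=str(meta["surface_id"]),
                    displacements=tuple(near["displacement_um"]),
                    apparent_zeta=tuple(near["zeta_mV"]),
                    zeta_far=float(grp.loc[far, "zeta_mV"].mean()),
                    tracer=str(meta.get("tracer", "standard")),
                    nacl_mM=float(meta.get("nacl_mM", 0.0)),
                )
            )
        else:
            profiles.append(
                profile_from_points(
                    str(meta["surface_id"]),
                    grp["displacement_um"].to_numpy(),
                    grp["zeta_mV"].to_numpy(),
                    tracer=str(meta.get("tracer", "standard")),
                    nacl_mM=float(meta.get("nacl_mM", 0.0)),
                    far_field_um=FAR_FIELD_UM,
                )
            )
    return profiles


def read_adhesion_table(path: str | Path) -> list[AdhesionRecord]:
    """Read adhesion replicate CSV into records."""
    df = pd.read_csv(path)
    _require_columns(df, {"surface_id", "material", "ra_um", "eps_type", "mass_ug", "area_cm2"}, path)
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                AdhesionRecord(
                    surface_id=str(row["surface_id"]),
                    material=str(row["material"]),
                    ra=float(row["ra_um"]),
                    eps_type=str(row["eps_type"]),
                    mass_adhered=float(row["mass_ug"]),
                    area=float(row["area_cm2"]),
                    replicate=int(row["replicate"]) if "replicate" in df.columns else 0,
                )
            )
        except (TypeError, ValueError):
            raise InputError(f"{path}: malformed adhesion row {idx + 2}") from None
    return records


def characterize_angles(angles: list[AngleSet], config: RunConfig) -> pd.DataFrame:
    """Per-surface characterization table from mean contact angles."""
    rows = []
    for aset in angles:
        result = solve_components(aset, config.liquids)
        profile = wetting_profile(
            aset, config.liquids, config.vogler_threshold, config.baier_interval
        )
        if any(result.root_sign_flags):
            log.warning(
                "%s: negative root in acid-base solve (plus=%s, minus=%s); "
                "magnitude convention applied",
                aset.surface_id,
                *result.root_sign_flags,
            )
        if profile.gamma_c_r2 < 0.9:
            log.warning(
                "%s: Zisman fit r^2 = %.3f < 0.9; gamma_c unreliable",
                aset.surface_id,
                profile.gamma_c_r2,
            )
        rows.append(
            {
                "surface_id": aset.surface_id,
                "theta_w": aset.theta_w,
                "theta_f": aset.theta_f,
                "theta_d": aset.theta_d,
                "gamma_lw": result.gamma_lw,
                "gamma_plus": result.gamma_plus,
                "gamma_minus": result.gamma_minus,
                "gamma_ab": result.gamma_ab,
                "gamma_s": result.gamma_s,
                "delta_g_coh": result.delta_g_coh,
                "tau0": profile.tau0,
                "gamma_c": profile.gamma_c,
                "gamma_c_r2": profile.gamma_c_r2,
                "vogler_class": profile.vogler_class,
                "baier_in_minimum": profile.baier_in_minimum,
                "root_sign_plus": result.root_sign_flags[0],
                "root_sign_minus": result.root_sign_flags[1],
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def zeta_report(profiles: list[ZetaProfile]) -> pd.DataFrame:
    """Per-profile surface-zeta table (zeta_s, intercept, slope)."""
    rows = []
    for p in profiles:
        zs, intercept, slope = surface_zeta(p)
        rows.append(
            {
                "surface_id": p.surface_id,
                "tracer": p.tracer,
                "nacl_mM": p.nacl_mM,
                "zeta_s_mV": zs,
                "intercept_mV": intercept,
                "slope_mV_per_um": slope,
                "zeta_far_mV": p.zeta_far,
            }
        )
    return pd.DataFrame(rows)


def run_characterization(
    config: RunConfig,
    angle_path: str | Path,
    zeta_path: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Full pipeline: angles (required) plus optional zeta section.

    Returns a dict of named report tables; an empty angle table yields an
    empty report with a warning rather than an error.
    """
    angles = read_angle_table(angle_path)
    if not angles:
        log.warning("%s: no surfaces found; empty report", angle_path)
        return {"characterization": pd.DataFrame(columns=REPORT_COLUMNS)}
    log.info("characterizing %d surface(s)", len(angles))
    out = {"characterization": characterize_angles(angles, config)}
    if zeta_path is not None:
        out["zeta"] = zeta_report(read_zeta_table(zeta_path))
    return out


def write_report(df: pd.DataFrame, path: str | Path) -> None:
    """Write a report table as CSV (UTF-8, header, decimal point)."""
    df.to_csv(path, index=False)
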