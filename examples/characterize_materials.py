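"""Characterize commercial photobioreactor materials from mean contact angles.

Builds the published mean-angle table for six untreated commercial
surfaces, inverts the three-liquid acid-base equations for each, and
prints the derived wettability metrics.
"""

import pandas as pd

from pbrsurf import AngleSet, default_liquid_set, solve_components, wetting_profile

ANGLES = {
    # surface: (theta_water, theta_formamide, theta_diiodomethane), degrees
    "GS (borosilicate glass)": (25, 26, 38),
    "PC (polycarbonate)": (78, 70, 26),
    "PE (polyethylene)": (97, 84, 55),
    "PETG": (81, 79, 27),
    "PMMA (acrylic)": (66, 61, 43),
    "PVC": (91, 64, 30),
}

liquids = default_liquid_set()
rows = []
for name, (tw, tf, td) in ANGLES.items():
    aset = AngleSet(name, tw, tf, td)
    energy = solve_components(aset, liquids)
    wet = wetting_profile(aset, liquids)
    rows.append(
        {
            "surface": name,
            "gamma_s": round(energy.gamma_s, 1),
            "dG_coh": round(energy.delta_g_coh, 1),
            "tau0": round(wet.tau0, 1),
            "class": wet.vogler_class,
            "neg_root": energy.root_sign_flags[0],
        }
    )

print(pd.DataFrame(rows).to_string(index=False))
print(
    "\ngamma_s: total surface free energy (mJ/m^2); dG_coh: cohesion free energy in\n"
    "water (positive = hydrophilic); tau0: water adhesion tension, > 30 mJ/m^2 is\n"
    "hydrophilic by Vogler's criterion; neg_root flags monopolar surfaces whose\n"
    "acid square root solved negative (magnitude convention applied).\n"
    "Only glass is hydrophilic here; the hydrophobic polymers (PE, PVC) are the\n"
    "better anti-biofouling candidates."
)
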