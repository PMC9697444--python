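"""End-to-end synthetic pipeline: generate noisy angles, recover components.

Generates triplicate contact angles for the six reference materials
(2-degree replicate noise), aggregates replicates, inverts the acid-base
equations and compares the recovered total surface energy with the truth
the generator used.
"""

import io

import pandas as pd

from pbrsurf import REFERENCE_MATERIALS, SynthConfig, generate_contact_angles
from pbrsurf.io import RunConfig, characterize_angles, read_angle_table

cfg = SynthConfig(seed=1, angle_sd=2.0, n_replicates=3)
angles = generate_contact_angles(cfg)
sets = read_angle_table(io.StringIO(angles.to_csv(index=False)))
report = characterize_angles(sets, RunConfig())

truth = {
    name: glw + 2 * (gp * gm) ** 0.5 for name, (glw, gp, gm) in REFERENCE_MATERIALS.items()
}
report = report[["surface_id", "gamma_s", "delta_g_coh", "tau0", "vogler_class"]].copy()
report["true_gamma_s"] = report["surface_id"].map(truth)
print(report.round(1).to_string(index=False))
print(
    "\nRecovered gamma_s should sit within a few mJ/m^2 of true_gamma_s: the\n"
    "2-degree replicate noise on three angles propagates to roughly that level\n"
    "after triplicate averaging."
)
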