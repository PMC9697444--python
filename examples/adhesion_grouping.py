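"""Control-normalized EPS adhesion with ANOVA/LSD letter groups.

Simulates triplicate BSA adhesion on three materials (one adhering 50%
more than the glass control), normalizes to the control surface density
and groups treatments by one-way ANOVA with Fisher's LSD at 95%.
"""

import pandas as pd

from pbrsurf import SynthConfig, anova_lsd, generate_adhesion, relative_adhesion
from pbrsurf.io import read_adhesion_table
import io

cfg = SynthConfig(seed=7, adhesion_cv=0.03, ra_levels=(0.1,),
                  materials={"GS": (1, 0, 0), "PC": (1, 0, 0), "PETG": (1, 0, 0)})
table = generate_adhesion(cfg, mean_relative={"PC": 1.0, "PETG": 1.5}, eps_types=("BSA",))

records = read_adhesion_table(io.StringIO(table.to_csv(index=False)))
controls = [r for r in records if r.material == "GS"]
m_ctl = sum(r.mass_adhered for r in controls) / len(controls)

groups: dict[str, list[float]] = {}
for r in records:
    groups.setdefault(r.material, []).append(relative_adhesion(r, m_ctl, controls[0].area))

res = anova_lsd(groups)
out = pd.DataFrame(
    {
        "material": list(groups),
        "mean_pct": [round(pd.Series(v).mean(), 1) for v in groups.values()],
        "letters": [res.letters[k] for k in groups],
    }
)
print(out.to_string(index=False))
print(f"\nF = {res.f_statistic:.1f}, p = {res.p_value:.2e}, LSD = {res.lsd:.1f}%")
print(
    "\nmean_pct is adhered mass per area as % of the glass control; materials\n"
    "sharing a letter are statistically indistinguishable at the 95% level.\n"
    "PETG (set to 1.5x the control) separates from GS and PC."
)
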