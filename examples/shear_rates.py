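"""Shear rates at the bottom of an orbiting Petri dish.

Protein/polysaccharide adhesion protocols run in dishes on an orbital
shaker; the wall shear rate controls both adsorption transport and
shear damage to the adsorbing macromolecules (polysaccharides degrade
above ~1000 1/s).
"""

from pbrsurf import shear_rate_table

table = shear_rate_table([50, 100, 150])
print(table.round(0).to_string(index=False))
print(
    "\ngamma_omega (1/s) for water at room temperature with the default\n"
    "effective orbital length of 0.0275 m. At 150 rpm the shear exceeds the\n"
    "~1000 1/s damage threshold for polysaccharides, which is why adsorption\n"
    "steps run at 100 rpm."
)
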