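"""Compile liquid-handler picklists for a robotic assembly batch.

Shows the three core steps: oligo hydration volumes, PCR plate packing
(92 reactions per 96-well plate, ladder wells A1/H12 reserved), and
equimolar fragment mixing for the digestion reaction.
"""

import pandas as pd

from agoassembly import (
    PcrReaction,
    equimolar_mix_picklist,
    generate_concentration_table,
    hydration_picklist,
    pcr_setup_picklists,
)
from agoassembly.fixtures import FixtureSpec, generate_design
from agoassembly.worklists import wells_column_major

# 1. hydrate lyophilized oligos to 100 uM
sheet = pd.DataFrame({"well": ["A1", "B1", "C1"], "nmol": [10.0, 2.5, 7.2]})
hydr = hydration_picklist(sheet, target_conc_uM=100.0)
print("hydration volumes (uL):", [r.volume for r in hydr.rows])

# 2. pack a 150-reaction batch into PCR plates
src = wells_column_major(384, skip=())
reactions = [PcrReaction(name=f"rx{i}", fwd_well=src[i], rev_well=src[i + 1],
                         template_well=src[i + 2]) for i in range(150)]
picklists, layouts = pcr_setup_picklists(reactions)
print("plate occupancy:", [len(l.contents) for l in layouts],
      "(A1/H12 reserved for ladder)")

# 3. equimolar mixing: mass proportional to length, 1 ug total
design = generate_design(FixtureSpec(n_fragments=5, gc_target=0.5, seed=7))
conc = generate_concentration_table(design, seed=7)
acoustic, tips, errors = equimolar_mix_picklist(
    conc, {f.id: len(f) for f in design.fragments}, total_mass_ng=1000.0
)
for r in acoustic.rows:
    print(f"  {r.comment}: {r.volume:8.1f} nL (acoustic)")
for r in tips.rows:
    print(f"  {r.comment}: {r.volume:8.3f} uL (tip-based)")
# Sub-3-uL transfers route to the acoustic dispenser (volumes in nL);
# equal molar amounts follow from mass proportional to fragment length.
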