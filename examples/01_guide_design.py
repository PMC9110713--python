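"""Design recognition sites and DNA guides for a 5-fragment plasmid.

Builds a synthetic 5-fragment circular design, scans each junction's
80-nt search space for a 24-bp recognition sequence passing the
digestion and ligation rules, and prints the chosen window, the two
16-nt guides, the 12-nt sticky end, and the suggested nuclease mode.
"""

from agoassembly import select_sites
from agoassembly.fixtures import FixtureSpec, generate_design

design = generate_design(FixtureSpec(n_fragments=5, gc_target=0.5, seed=7))
select_sites(design)

print(f"{design.name}: {design.n_fragments} fragments, {len(design)} bp circle\n")
for j in design.junctions:
    s = j.chosen_site
    print(f"junction {j.index} ({j.upstream_fragment_id} -> {j.downstream_fragment_id})")
    print(f"  window offset {s.window_offset:2d}  {s.sequence24}")
    print(f"  guide_top    {s.guide_top}")
    print(f"  guide_bottom {s.guide_bottom}")
    print(f"  sticky end   {s.sticky_end}  mode {s.enzyme_mode.value}")

# Offset 28 centers the window on the fragment boundary; each guide pair
# programs one double-strand cut leaving the central 12-mer as a 5'
# overhang, and no two junctions share (or nearly share) an overhang.
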