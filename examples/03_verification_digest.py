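"""Pick verification digests and match predicted to observed bands.

Ranks single/double restriction digests whose band patterns separate
cleanly on a capillary electrophoresis instrument, then demonstrates
matching a (simulated) observed band list against the prediction at the
instrument's 10% sizing accuracy.
"""

from agoassembly import match_bands, select_combinations
from agoassembly.fixtures import FixtureSpec, generate_design

design = generate_design(FixtureSpec(n_fragments=5, gc_target=0.5, seed=7))
plans = select_combinations(design.target_sequence, plasmid_name=design.name)

print(f"{design.name} ({len(design)} bp): {len(plans)} accepted digest plans")
for plan in plans[:5]:
    print(f"  {'+'.join(plan.enzymes):<16} bands {plan.predicted_bands}")

best = plans[0]
observed = [round(b * 1.04) for b in best.predicted_bands]  # 4% sizing error
verdict = match_bands(best.predicted_bands, observed, tolerance=0.1)
print(f"\nobserved {observed} vs predicted {best.predicted_bands}: "
      f"{'match' if verdict.passed else 'mismatch'}")
# Accepted plans satisfy: smallest band >= 100 bp, largest <= 9500 bp,
# adjacent bands differing by at least 0.1 x the larger band.
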