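# agoassembly

Design toolkit for scarless multi-fragment plasmid assembly with
DNA-guided Argonaute nucleases (artificial restriction enzymes, AREs).

A thermophilic Argonaute loaded with a pair of short single-stranded DNA
guides cleaves double-stranded DNA at a programmable site, so any 24-bp
*recognition sequence* can act as a restriction site: two 16-nt guides
direct staggered cuts that leave a 12-nt 5′ overhang.  Fragments
amplified with primers whose tails install a shared recognition sequence
at each junction can therefore be digested and re-ligated into a
circular plasmid with no scar — the overhang *is* plasmid sequence.

Given an ordered set of DNA fragments defining a circular target, the
toolkit automates the full design:

- **Guide design** — for every junction, scan the 80-nt search space
  (40 bp each side of the fragment boundary, 57 candidate 24-bp windows)
  and pick the first window passing the digestion rules (GC ≤ 75 %, no
  G-quadruplex, no run of >4 A or T, overhang/guide k-mers unique in the
  plasmid) and the ligation rules (non-palindromic sticky end,
  orthogonal to every previously chosen end under a ligase mismatch
  fidelity model); suggest wild-type + mutant or mutant-only nuclease by
  GC content.
- **Primer design** — 18-bp starting binding sites resized by GC,
  forward/reverse melting temperatures balanced to within 1 °C under a
  nearest-neighbor Tm model (unified SantaLucia ΔH/ΔS, salt-corrected),
  5′ tails installing the 24-bp junction homology; a two-round extended
  primer workflow absorbs fragments shorter than 80 bp.
- **Verification digests** — in-silico restriction digestion of the
  circular product; accepted enzyme combinations give bands in
  [100, 9500] bp with adjacent bands separated by at least 0.1 × the
  band size; batch-wide common enzymes and predicted-vs-observed band
  matching.
- **Assembly simulation** — exact-string PCR, guide-directed digestion
  and ligation under the fidelity model; a round-trip check proves each
  design reassembles into precisely the target sequence (and enumerates
  misassembly products when overhangs are deliberately degenerate).
- **Worklists** — acoustic/tip liquid-handler picklists for oligo
  hydration, PCR setup (92 reactions per 96-well plate, ladder wells
  A1/H12 reserved), equimolar fragment mixing (mass ∝ length), and
  failed-PCR consolidation.

A seeded fixture generator produces synthetic designs (fragment count,
sizes, GC content, planted repeats all controlled), so the whole
pipeline is testable without any external data.

## Worked example

```python
from agoassembly import design_primers, round_trip_check, select_sites
from agoassembly.fixtures import FixtureSpec, generate_design

design = generate_design(FixtureSpec(n_fragments=5, gc_target=0.5, seed=7))
select_sites(design)
site = design.junctions[0].chosen_site
print(site.window_offset, site.sequence24, site.sticky_end)

primers = design_primers(design)
print(round(max(p.delta_tm for p in primers.values()), 3))
print(round_trip_check(design, primers).passed)
```

prints

```
28 TAGTGGAGATAGGTTGTGTAAAGG AGATAGGTTGTG
0.584
True
```

Junction 0's recognition window sits at offset 28 — centered on the
fragment boundary, so each neighbouring amplicon contributes a 12-nt
tail — and leaves the 5′ overhang `AGATAGGTTGTG`.  Every primer pair is
Tm-balanced to within 0.584 °C (rule: ≤ 1 °C), and the simulated
digestion–ligation reassembles the 10,342-bp circle with zero sequence
difference: the design is scarless.

The `examples/` scripts walk each capability (guide design, primers +
simulation, verification digests, worklists) with commentary, and the
`agoassembly` CLI wraps the same functions for shell use
(`agoassembly fixture | load | design | primers | check-ends |
verify-plan | match-bands | simulate`).

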