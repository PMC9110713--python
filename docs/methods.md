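# Methods

## The assembly chemistry being modelled

A DNA-guided Argonaute nuclease programmed with two 16-nt ssDNA guides
cleaves a 24-bp double-stranded recognition sequence with staggered
cuts, leaving 12-nt 5′ overhangs.  Adjacent PCR amplicons that share a
24-bp terminal recognition sequence can be digested in one pot and
ligated by a high-fidelity thermostable ligase; because the overhang is
plasmid sequence (not an added linker), the junction is scarless.  The
toolkit designs every component of that scheme and proves each design
correct by simulation.

## Coordinates and data model

All coordinates are 0-based, half-open, on the top strand; circular
positions are reduced modulo the plasmid length.  Fragments are stored
*without* the shared 24-bp overlaps — raw fragments abut exactly, and
the overlaps are introduced by primer tails.  Junction *i* sits between
fragment *i* and fragment *i+1* (wrapping), and owns an 80-nt search
space: the last 40 nt of the upstream fragment + the first 40 nt of the
downstream one.

## Cut geometry and guide derivation

The nuclease cleaves its target strand between the bases opposite guide
positions 10 and 11 (counted from the guide 5′ end).  Placing the two
guides flush with the window edges — `guide_top = revcomp(window[0:16])`
pairing the top strand, `guide_bottom = window[8:24]` pairing the bottom
strand — puts the top-strand cut after window index 5 and the
bottom-strand cut after index 17, so the central 12-mer `window[6:18]`
becomes the 5′ overhang.  The exact in-window placement of the guides is
not uniquely determined by the chemistry as published; this symmetric
convention is validated structurally instead: the simulator's digestion
of any amplicon reproduces the derived sticky end exactly (a round-trip
invariant exercised over 1,000 random windows in the test suite).  Guide
length, cut offset and window length are all configurable
(`CutGeometry`), with the constraint that the two cuts leave a positive
5′ overhang.

## Guide selection

Candidates are the 57 sliding 24-bp windows of the 80-nt search space,
scanned center-outward (offset 28, then 27, 29, 26, 30, …).  The scan
order is a design choice — the first acceptable window wins, and
starting at the boundary keeps primer tails near their minimum of 12 nt
per side.  A window must pass, in order:

1. **GC content** in [0, 0.75].  The upper bound reflects the nuclease's
   observed cleavage range; windows near ~80 % GC fail to cleave.
2. **No G-quadruplex** on either strand, motif
   `G{3,}(N{1,7}G{3,}){3}` — the standard minimal G4 rule; the criterion
   is named in the method's source but no rule is printed, so the regex
   parameters are config-exposed.
3. **No homopolymer run of more than 4 A or 4 T** (runs of exactly 4
   pass; A-runs and T-runs are tested separately, not mixed A/T runs).
4. **Off-target uniqueness**: the 12-mers that become new DNA ends (the
   sticky end and its complement) and each strand cut's spanning 12-mer
   must occur nowhere in the indexed library (plasmid both strands +
   PCR templates) outside the junction's own window.  The index stores
   occurrence positions, so the intended locus — including its copy
   inside a template fragment — is excluded by coordinate.  k = 12
   matches the functional unit (the overhang) and is configurable.  The
   library indexes only the design and its templates, not a host
   genome.

A passing window is then checked against the **ligation criteria**
before being finalized: its sticky end must be non-palindromic (a
palindromic 5′ overhang self-ligates), must not duplicate any earlier
junction's cognate pair, and every non-cognate pairing among all chosen
ends (including self-pairings) must score below the fidelity threshold.
Selection is greedy and sequential by junction index, hence fully
deterministic for a given design and configuration; if all 57 windows
fail, the error carries the complete per-window filter report.

### Nuclease mode

Wild-type and engineered-mutant Argonautes differ in GC affinity: the
wild type cleaves best at very low GC (≲10 %), the mutant at ≳50 %, and
only the mutant handles very high-GC substrates.  The mode suggestion is
threshold-based: any fragment with GC ≥ 0.65 forces mutant-only,
otherwise the one-pot wild-type + mutant mix is suggested, with a
per-window preference annotation (wt ≤ 0.10 / mutant ≥ 0.50 / neutral).
The thresholds are qualitative readings of the cleavage-efficiency data
and are all configurable.

## Ligation fidelity model

Overhang pairing is scored per position, ungapped and antiparallel:
`score(a, b) = Σᵢ w(a[i], b[11−i])` over a 4×4 weight table with
Watson–Crick = 1, so a cognate pair scores exactly 12.  The shipped
table (`data/hifi_taq_mismatch_synthetic.tsv`) is a **synthetic
stand-in** with the qualitative shape of a thermostable-ligase mismatch
profile — G·T wobble 0.3, all other mismatches 0.05 — because the
measured profile is not reproduced here; users can substitute any
16-row TSV.  The default acceptance threshold of 8.0/12 is likewise a
placeholder for the unpublished value.  Ungapped scoring is intentional:
ligation joins ends in register, and out-of-register annealing is
already excluded by the off-target 12-mer uniqueness rule.

## Primer design

Binding regions anchor at the amplicon's annealing position on the raw
fragment (usually the terminus; a window reaching more than 40 nt into a
fragment shifts the anchor inward).  Sizing starts at 18 bp: AT-rich
starts (GC < 0.40) extend 3′-ward up to 30 bp toward a Tm floor, GC-rich
starts (GC > 0.60) may shrink to 15 bp while the floor holds.  Balancing
then searches the full [15, 30]² length grid for the pair minimizing
|ΔTm| subject to |ΔTm| ≤ 1 °C, preferring pairs meeting the floor on
both sides and, within 0.25 °C delta buckets, hotter pairs.  When the
two termini differ too sharply in composition for the standard grid
(observed on seeded fixtures: an AT-rich forward terminus peaking at
53 °C against a GC-rich reverse terminus bottoming at 56 °C), the search
widens once to [12, 36] — the Tm engine's validity range — and flags the
pair; only if that also fails is the pair reported infeasible with the
best achievable |ΔTm|.

Tm is computed on the binding region only (tails excluded), with the
unified SantaLucia (1998) nearest-neighbor ΔH/ΔS set, terminal
initiation terms, entropic salt correction
ΔS′ = ΔS + 0.368 (N−1) ln[Na⁺]eff, divalent ions folded in as
[Na⁺]eff = [mono] + 120·√([Mg²⁺]−[dNTP]) (mM), and
Tm = ΔH/(ΔS′ + R ln(Cₜ/4)) − 273.15 at Cₜ = 50 nM.  The engine agrees
with an independent nearest-neighbor implementation to well under
0.5 °C across random primers (test-enforced).  Defaults — floor 58 °C,
bounds [15, 30], GC branch points 0.40/0.60 — are conventional choices,
all config-exposed.  Under the default 50 mM monovalent / 50 nM primer
parameterization, mid-GC 18-mers sit near 50–53 °C, so the 58 °C floor
frequently drives extension toward 24–30 bp; that is expected behaviour,
not an error.

### Overhang geometry

With the left junction window at offset w within its search space, the
amplicon starts 40 − w bases before the fragment (forward tail of that
length) or, for w > 40, the binding site shifts w − 40 bases inward;
symmetrically the right window at offset w ends w − 16 bases past the
fragment end.  Adjacent amplicons therefore share exactly the 24-bp
recognition sequence, and concatenating amplicons with each shared 24-mer
counted once reproduces the target circle — the invariant behind the
scarlessness guarantee.  Tails longer than 40 nt draw a synthesis
practicality warning.

### Fragments under 80 bp

A linker too short to host junctions on both sides is absorbed into its
downstream neighbour (deterministic default), and the junction set is
rebuilt over the merged fragment.  The merged fragment's long forward
tail is split across two PCR rounds: round 1 amplifies the host with the
linker half nearest it; round 2 uses the round-1 product as template and
adds the remaining half plus the junction overhang.  The two-round
product is string-identical to the merged amplicon (test-enforced).

## Verification digests

Sites are located by IUPAC-expanded regex on the doubled sequence (so
sites spanning the origin are found), on both strands; each duplex site
yields exactly one cleavage coordinate (top-strand cut).  Band sizes are
inter-cut distances on the circle and always sum to the plasmid length.
Single and double digests are evaluated against: smallest band ≥ 100 bp,
largest ≤ 9500 bp, adjacent bands differing by ≥ A × band size with
A = 0.1 (the electrophoresis instrument's sizing accuracy).  "Band size"
in the gap rule is taken as the **larger** of the adjacent pair — the
conservative reading, switchable by config.  Accepted plans rank by band
count (more informative patterns first), then by minimum gap ratio.
Combinations are capped at two enzymes.  The shipped enzyme table is a
~35-entry stand-in of common palindromic 6/8-cutters in a replaceable
TSV; nicking and methylation sensitivity are not modelled.  Band
matching is greedy one-to-one in sorted order at 10 % relative tolerance
with a 50-bp noise floor for unexplained observed peaks.

## Assembly simulation

PCR is exact string extraction — primers are incorporated verbatim (so
an injected primer mutation propagates to a localized product diff);
no polymerase error model.  Digestion applies the two strand cuts at
each terminal window, tracking retained strands, overhangs and released
terminal oligos; per-strand base counts are conserved.  Ligation joins a
right overhang to a left overhang when perfectly complementary
(strict mode) or when the fidelity score meets the threshold
(misassembly-prediction mode), and enumerates simple directed cycles —
circular products using each fragment at most once, orientation
preserved.  Head-to-head inversions and concatemers are out of scope
(combinatorial blowup; not needed for the orthogonality argument).  A
released oligo necessarily contains its own junction's sticky end, so
re-ligation risk is flagged only when a released oligo contains a
*different* junction's overhang (cross-talk); on filter-passing designs
this list is empty by construction.

The round-trip check — PCR → digestion → strict ligation → compare the
single circular product with the target up to rotation/reflection — is
the package's definition of a correct design, and holds across the
tested envelope: 1–11 fragments, GC 0.35–0.75, with and without four
planted 500-bp repeats.

## Synthetic designs (fixture generator)

Fragment sequences are i.i.d. base draws with P(G) = P(C) = gc/2 and a
rejection loop enforcing realized GC within ±3 percentage points per
fragment; sizes are uniform in the requested range (defaults 800–2500 bp,
5 fragments — a typical mid-size assembly; the tested envelope spans
1–11 fragments and up to ~77 % GC, mirroring realistic jobs).  Repeats
are planted as an identical subsequence in `n_repeats` distinct
fragments, never within 40 bp of a fragment end, so search spaces stay
repeat-free by construction — internal repeats are exactly what this
junction-local design method tolerates.  One integer seed drives a named
substream per component (sizes, bases, repeat, placement,
concentrations), so adding a component never perturbs the others and
equal seeds give byte-identical output.

What the generator does *not* emulate: real promoter/gene composition,
compositional heterogeneity along a fragment, synthesis or PCR errors,
and host-genome off-target context.  Passing tests therefore demonstrate
the design algebra and its guarantees, not wet-lab success rates — which
depend on cleavage efficiency, ligase fidelity and transformation, none
of which are modelled quantitatively here.

## Numerical and degenerate-input choices

- Validation rejects ambiguity codes and U at load; lowercase is
  uppercased.
- Canonical circular comparison = lexicographically smallest rotation of
  the sequence or its reverse complement (O(n²) scan; plasmids are
  small).
- Single-fragment designs are legal: one wrap-around junction joins the
  fragment's tail to its own head and the amplicon is the full circle
  plus one 24-mer.
- A digest with one cut reports one full-length band; with none, an
  empty band list flagged `no_cut`.
- Equimolar mixing writes full-precision volumes (mass ∝ length makes
  molar amounts exactly equal; the instrument quantizes at dispense
  time); volumes below the 2.5 nL acoustic granularity are error rows,
  and sub-3-µL transfers route acoustic (nL) versus tip-based (µL).
- dsDNA molar mass is approximated as 657 g·mol⁻¹·bp⁻¹.
- PCR plates fill column-major (A1→H1, A2→…) skipping the reserved
  ladder wells A1/H12, 92 reactions per plate; fill order is a
  convention, the capacity and reservations are the protocol's.

## Known limitations

- The fidelity table and its threshold are placeholders pending a
  measured ligase profile; orthogonality verdicts are qualitative.
- No thermodynamic model of cleavage efficiency or position-dependent
  base preference; the GC thresholds are step functions.
- No primer-dimer or secondary-structure screening.
- Off-target indexing covers the design and templates only, not a host
  genome.
- Sticky-end length is fixed at 12 nt (the shipped chemistry);
  alternative overhang lengths are expressible through `CutGeometry`
  but untested beyond the round-trip invariant.
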