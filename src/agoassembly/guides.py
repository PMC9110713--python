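"""Guide design: 24-bp recognition sites, digestion filters, enzyme choice.

For each junction the 80-nt search space (40 nt each side of the fragment
boundary) is scanned for 24-bp recognition windows.  A window passing the
digestion filters (GC content, G-quadruplex, A/T homopolymers, off-target
k-mer uniqueness) and the ligation criteria (non-palindromic sticky end,
orthogonality against already-finalized ends) is finalized; its two 16-nt
DNA guides and 12-nt 5' sticky end follow from the cut geometry.

Cut geometry.  The Argonaute nuclease cleaves its target strand between
the bases opposite guide positions 10 and 11 (counting from the guide
5' end).  Placing the two 16-nt guides flush with the window edges —
guide_top pairing top-strand window[0:16], guide_bottom pairing the
bottom strand of window[8:24] — puts the top-strand cut after window
index 5 and the bottom-strand cut after index 17, leaving the central
12-mer window[6:18] as a 5' overhang.  The geometry is configurable and
is validated by the digestion round-trip invariant, not assumed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .core import (
    JUNCTION_HOMOLOGY,
    PlasmidDesign,
    gc_content,
    revcomp,
    validate_dna,
)
from .errors import DesignInfeasibleError, ValidationError
from .fidelity import FidelityModel, STICKY_LEN, orthogonality_check

WINDOW_LEN = JUNCTION_HOMOLOGY  # 24


class EnzymeMode(str, Enum):
    WT_AND_MUTANT = "wt_and_mutant"
    MUTANT_ONLY = "mutant_only"


class GCPreference(str, Enum):
    WT_PREFERRED = "wt_preferred"
    MUTANT_PREFERRED = "mutant_preferred"
    NEUTRAL = "neutral"


@dataclass(frozen=True)
class CutGeometry:
    """Guide length and guide-5'-anchored cut offset defining the overhang."""

    guide_length: int = 16
    cut_from_guide5: int = 10  # scissile bond between guide positions 10|11
    window_length: int = WINDOW_LEN

    def __post_init__(self):
        if not 0 < self.cut_from_guide5 < self.guide_length:
            raise ValidationError("cut_from_guide5 must lie inside the guide")
        if self.guide_length > self.window_length:
            raise ValidationError("guide cannot be longer than the recognition window")
        if self.top_cut >= self.bottom_cut:
            raise ValidationError(
                "geometry leaves no 5' overhang (top cut at/after bottom cut)"
            )

    @property
    def top_cut(self) -> int:
        """Top-strand cut position in window coordinates (cut after index-1)."""
        return self.guide_length - self.cut_from_guide5

    @property
    def bottom_cut(self) -> int:
        return self.window_length - self.top_cut

    @property
    def overhang_length(self) -> int:
        return self.bottom_cut - self.top_cut


DEFAULT_GEOMETRY = CutGeometry()
assert DEFAULT_GEOMETRY.overhang_length == STICKY_LEN


def derive_guides(window: str, geometry: CutGeometry = DEFAULT_GEOMETRY):
    """(guide_top, guide_bottom, sticky_end) for one recognition window.

    guide_top is the ssDNA guide directing the top-strand cut (it is the
    reverse complement of the top strand it pairs with); guide_bottom
    directs the bottom-strand cut and therefore reads as top-strand
    sequence.  The two guides jointly cover the full window.
    """
    window = validate_dna(window, context="recognition window")
    if len(window) != geometry.window_length:
        raise ValidationError(
            f"recognition window must be {geometry.window_length} nt, got {len(window)}"
        )
    g = geometry.guide_length
    guide_top = revcomp(window[:g])
    guide_bottom = window[geometry.window_length - g :]
    sticky = window[geometry.top_cut : geometry.bottom_cut]
    return guide_top, guide_bottom, sticky


@dataclass
class FilterOutcome:
    name: str
    passed: bool
    value: object
    detail: str = ""


@dataclass
class FilterReport:
    window_offset: int
    sequence24: str
    outcomes: list = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(o.passed for o in self.outcomes)

    def outcome(self, name: str) -> FilterOutcome:
        for o in self.outcomes:
            if o.name == name:
                return o
        raise KeyError(name)

    def failures(self) -> list:
        return [o for o in self.outcomes if not o.passed]


@dataclass
class DigestionCriteria:
    """Thresholds for the per-window digestion filters and enzyme choice."""

    gc_min: float = 0.0
    gc_max: float = 0.75
    max_at_run: int = 4  # runs strictly longer than this fail
    gquad_g_run: int = 3
    gquad_loop_max: int = 7
    offtarget_k: int = 12
    wt_preference_gc: float = 0.10
    mutant_preference_gc: float = 0.50
    mutant_only_fragment_gc: float = 0.65

    def __post_init__(self):
        if not 0.0 <= self.gc_min < self.gc_max <= 1.0:
            raise ValidationError("need 0 <= gc_min < gc_max <= 1")

    @property
    def gquad_regex(self) -> str:
        g, loop = self.gquad_g_run, self.gquad_loop_max
        return f"G{{{g},}}(?:[ACGT]{{1,{loop}}}G{{{g},}}){{3}}"


@dataclass(frozen=True)
class RecognitionSite:
    """A finalized 24-bp recognition sequence at one junction."""

    junction_index: int
    window_offset: int  # 0..56 within the 80-nt search space
    sequence24: str
    guide_top: str
    guide_bottom: str
    sticky_end: str
    enzyme_mode: EnzymeMode
    gc_preference: GCPreference = GCPreference.NEUTRAL
    filter_report: Optional[FilterReport] = None

    def __post_init__(self):
        if len(self.sequence24) != WINDOW_LEN:
            raise ValidationError("recognition sequence must be 24 nt")
        if len(self.guide_top) != 16 or len(self.guide_bottom) != 16:
            raise ValidationError("guides must be 16 nt")
        if len(self.sticky_end) != STICKY_LEN:
            raise ValidationError("sticky end must be 12 nt")
        if self.sticky_end not in self.sequence24:
            raise ValidationError("sticky end must be a substring of the window")


class OfftargetLibrary:
    """Positional k-mer index over the design and its PCR templates.

    Indexes every k-mer of each sequence's top strand (the circular target
    is scanned across its origin); lookups count hits of a k-mer and of its
    reverse complement, i.e. both strands.  A junction's own window span is
    excluded by coordinate, including its image inside template fragments.
    """

    def __init__(self, k: int = 12):
        self.k = k
        self._index: dict[str, list] = {}  # kmer -> [(seq_id, pos)]
        self._lengths: dict[str, int] = {}
        self._circular: dict[str, bool] = {}
        self._target_map: dict[str, int] = {}  # seq_id -> offset in target coords

    def add_sequence(self, seq_id: str, seq: str, *, circular: bool = False,
                     target_offset: int = None) -> None:
        seq = validate_dna(seq, context=seq_id)
        n = len(seq)
        self._lengths[seq_id] = n
        self._circular[seq_id] = circular
        if target_offset is not None:
            self._target_map[seq_id] = target_offset
        text = seq + seq[: self.k - 1] if circular else seq
        for i in range(len(text) - self.k + 1):
            self._index.setdefault(text[i : i + self.k], []).append((seq_id, i))

    @classmethod
    def from_design(cls, design: PlasmidDesign, k: int = 12,
                    include_templates: bool = True) -> "OfftargetLibrary":
        lib = cls(k=k)
        lib.add_sequence("__target__", design.target_sequence, circular=True)
        if include_templates:
            for frag in design.fragments:
                lib.add_sequence(
                    f"template:{frag.id}", frag.sequence,
                    target_offset=design.fragment_start(frag.id),
                )
        return lib

    def _in_span(self, seq_id: str, pos: int, span: tuple) -> bool:
        """Is the k-mer at (seq_id, pos) inside the excluded target span?"""
        if span is None:
            return False
        lo, hi = span  # target coords, hi may exceed target length (wraps)
        target_len = self._lengths.get("__target__")
        if seq_id == "__target__":
            coord = pos
        elif seq_id in self._target_map:
            coord = (self._target_map[seq_id] + pos) % (target_len or 1)
        else:
            return False
        if target_len:
            coord_unwrapped = coord if coord >= lo % target_len else coord + target_len
            lo_m = lo % target_len
            return lo_m <= coord_unwrapped and coord_unwrapped + self.k <= lo_m + (hi - lo)
        return lo <= coord and coord + self.k <= hi

    def hits_outside(self, kmer: str, exclude_span: tuple = None) -> list:
        """Occurrences of ``kmer`` on either strand outside the excluded span."""
        kmer = validate_dna(kmer)
        if len(kmer) != self.k:
            raise ValidationError(f"expected a {self.k}-mer")
        hits = []
        for probe, strand in ((kmer, "+"), (revcomp(kmer), "-")):
            for seq_id, pos in self._index.get(probe, []):
                if not self._in_span(seq_id, pos, exclude_span):
                    hits.append((seq_id, pos, strand))
        return hits


def build_search_space(design: PlasmidDesign, junction_index: int) -> str:
    """The 80-nt guide search space of one junction (recorded on the design).

    Last 40 nt of the upstream fragment + first 40 nt of the downstream
    fragment; the wrap-around junction spans the sequence origin.
    """
    junction = design.junctions[junction_index]
    if junction.search_space is None:
        raise ValidationError(
            f"junction {junction_index}: no search space (short linker not yet absorbed "
            "by the small-fragment workflow)"
        )
    return junction.search_space


def enumerate_candidates(search_space: str, *, center_out: bool = True) -> list:
    """All 24-nt windows of the search space as (offset, sequence) pairs.

    An 80-nt space yields 57 windows.  Scan order is center-outward from
    the fragment boundary (offset 28, then 27, 29, 26, 30, ...) so the
    first acceptable site keeps primer overhangs short; pass
    ``center_out=False`` for plain left-to-right order.
    """
    search_space = validate_dna(search_space, context="search space")
    L = len(search_space)
    if L < WINDOW_LEN:
        raise ValidationError(f"search space must be >= {WINDOW_LEN} nt, got {L}")
    n = L - WINDOW_LEN + 1
    if center_out:
        center = (L - WINDOW_LEN) // 2
        order, step = [center], 1
        while len(order) < n:
            for off in (center - step, center + step):
                if 0 <= off <= n - 1:
                    order.append(off)
            step += 1
    else:
        order = list(range(n))
    return [(off, search_space[off : off + WINDOW_LEN]) for off in order]


def _max_run(seq: str, base: str) -> int:
    best = run = 0
    for c in seq:
        run = run + 1 if c == base else 0
        best = max(best, run)
    return best


def apply_digestion_filters(
    window: str,
    criteria: DigestionCriteria = None,
    offtargets: OfftargetLibrary = None,
    *,
    window_offset: int = -1,
    exclude_span: tuple = None,
    geometry: CutGeometry = DEFAULT_GEOMETRY,
) -> FilterReport:
    """Evaluate the four digestion criteria on one 24-nt window.

    In order: (1) window GC within [gc_min, gc_max]; (2) no G-quadruplex
    motif on either strand; (3) no A-run and no T-run longer than
    ``max_at_run``; (4) the new DNA ends (sticky end and complement) and
    each guide's cut-spanning k-mer occur nowhere in the off-target
    library outside the intended locus.  Failures are verdicts in the
    report, never exceptions.
    """
    criteria = criteria or DigestionCriteria()
    window = validate_dna(window, context="window")
    if len(window) != WINDOW_LEN:
        raise ValidationError(f"window must be {WINDOW_LEN} nt")
    report = FilterReport(window_offset=window_offset, sequence24=window)

    gc = gc_content(window)
    report.outcomes.append(
        FilterOutcome(
            "gc", criteria.gc_min <= gc <= criteria.gc_max, round(gc, 4),
            f"bounds [{criteria.gc_min}, {criteria.gc_max}]",
        )
    )

    pattern = re.compile(criteria.gquad_regex)
    has_g4 = bool(pattern.search(window)) or bool(pattern.search(revcomp(window)))
    report.outcomes.append(
        FilterOutcome("gquad", not has_g4, has_g4, "G-quadruplex motif, either strand")
    )

    a_run, t_run = _max_run(window, "A"), _max_run(window, "T")
    report.outcomes.append(
        FilterOutcome(
            "homopolymer",
            a_run <= criteria.max_at_run and t_run <= criteria.max_at_run,
            {"max_A_run": a_run, "max_T_run": t_run},
            f"runs of more than {criteria.max_at_run} A or T fail",
        )
    )

    if offtargets is not None:
        _, _, sticky = derive_guides(window, geometry)
        half = offtargets.k // 2
        probes = {
            sticky,
            revcomp(sticky),
            # cut-spanning k-mers of the two strand cuts
            window[max(0, geometry.top_cut - half) : geometry.top_cut + half],
            revcomp(window[geometry.bottom_cut - half : geometry.bottom_cut + half]),
        }
        hits = []
        for probe in sorted(probes):
            if len(probe) == offtargets.k:
                hits.extend(offtargets.hits_outside(probe, exclude_span))
        report.outcomes.append(
            FilterOutcome("offtarget", not hits, len(hits),
                          "new-end and cut-spanning k-mers must be unique")
        )
    return report


def suggest_enzyme_mode(
    fragment_gcs: list,
    window_gc: float,
    criteria: DigestionCriteria = None,
):
    """Choose the nuclease mode for an assembly and annotate GC preference.

    High-GC fragments (any fragment at/above ``mutant_only_fragment_gc``)
    force the engineered mutant alone; otherwise the wild-type/mutant
    one-pot mix is suggested.  Per-window preference: wild-type at very
    low window GC, mutant at/above 50%, neutral between.
    """
    criteria = criteria or DigestionCriteria()
    for g in list(fragment_gcs) + [window_gc]:
        if not 0.0 <= g <= 1.0:
            raise ValidationError("GC fractions must be in [0, 1]")
    mode = (
        EnzymeMode.MUTANT_ONLY
        if fragment_gcs and max(fragment_gcs) >= criteria.mutant_only_fragment_gc
        else EnzymeMode.WT_AND_MUTANT
    )
    if window_gc <= criteria.wt_preference_gc:
        pref = GCPreference.WT_PREFERRED
    elif window_gc >= criteria.mutant_preference_gc:
        pref = GCPreference.MUTANT_PREFERRED
    else:
        pref = GCPreference.NEUTRAL
    return mode, pref


def select_sites(
    design: PlasmidDesign,
    criteria: DigestionCriteria = None,
    offtargets: OfftargetLibrary = None,
    fidelity: FidelityModel = None,
    geometry: CutGeometry = DEFAULT_GEOMETRY,
) -> PlasmidDesign:
    """Greedily finalize one recognition site per junction, in junction order.

    For each junction, candidates are scanned center-outward; the first
    window passing all digestion filters AND the ligation criteria against
    every previously finalized sticky end is finalized.  Deterministic:
    the same design and configuration always yield the same sites.

    Raises :class:`DesignInfeasibleError` with the complete per-window
    failure report when a junction admits no window.
    """
    criteria = criteria or DigestionCriteria()
    fidelity = fidelity or FidelityModel.packaged_default()
    if offtargets is None:
        offtargets = OfftargetLibrary.from_design(design, k=criteria.offtarget_k)
    fragment_gcs = [f.gc for f in design.fragments]
    chosen_sticky: list[str] = []
    total = len(design.target_sequence)

    for junction in design.junctions:
        space = build_search_space(design, junction.index)
        span = (junction.search_space_origin, junction.search_space_origin + len(space))
        reports = []
        found = None
        for offset, window in enumerate_candidates(space):
            win_start = junction.search_space_origin + offset
            win_span = (win_start % total, win_start % total + WINDOW_LEN)
            report = apply_digestion_filters(
                window, criteria, offtargets,
                window_offset=offset, exclude_span=win_span, geometry=geometry,
            )
            if not report.passed:
                reports.append(report)
                continue
            guide_top, guide_bottom, sticky = derive_guides(window, geometry)
            lig = orthogonality_check(chosen_sticky + [sticky], fidelity)
            if not lig.passed:
                report.outcomes.append(
                    FilterOutcome("ligation", False, lig.max_noncognate_score, lig.reason)
                )
                reports.append(report)
                continue
            report.outcomes.append(
                FilterOutcome("ligation", True, lig.max_noncognate_score, "orthogonal")
            )
            mode, pref = suggest_enzyme_mode(fragment_gcs, gc_content(window), criteria)
            found = RecognitionSite(
                junction_index=junction.index,
                window_offset=offset,
                sequence24=window,
                guide_top=guide_top,
                guide_bottom=guide_bottom,
                sticky_end=sticky,
                enzyme_mode=mode,
                gc_preference=pref,
                filter_report=report,
            )
            break
        if found is None:
            raise DesignInfeasibleError(
                f"junction {junction.index} ({junction.upstream_fragment_id} -> "
                f"{junction.downstream_fragment_id}): none of {len(reports)} candidate "
                "windows satisfies the design rules",
                reports=reports,
            )
        junction.chosen_site = found
        chosen_sticky.append(found.sticky_end)
    return design


def window_target_start(design: PlasmidDesign, junction_index: int) -> int:
    """Target coordinate of the chosen recognition window's first base."""
    junction = design.junctions[junction_index]
    if junction.chosen_site is None:
        raise ValidationError(f"junction {junction_index} has no finalized site")
    total = len(design.target_sequence)
    return (junction.search_space_origin + junction.chosen_site.window_offset) % total


def sites_summary(design: PlasmidDesign) -> list:
    """Per-junction dicts (JSON-ready) for finalized designs."""
    rows = []
    for j in design.junctions:
        s = j.chosen_site
        if s is None:
            continue
        rows.append(
            {
                "junction_index": j.index,
                "upstream": j.upstream_fragment_id,
                "downstream": j.downstream_fragment_id,
                "window_offset": s.window_offset,
                "sequence24": s.sequence24,
                "guide_top": s.guide_top,
                "guide_bottom": s.guide_bottom,
                "sticky_end": s.sticky_end,
                "enzyme_mode": s.enzyme_mode.value,
                "gc_preference": s.gc_preference.value,
            }
        )
    return rows
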