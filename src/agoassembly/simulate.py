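"""In-silico execution of the digestion–ligation assembly chemistry.

Each amplicon carries a full 24-bp recognition sequence at each terminus.
Guide-directed digestion applies the two strand cuts of the cut geometry,
releasing short terminal oligos and leaving a 12-nt 5' overhang at each
end.  Ligation then joins overhangs — either strictly Watson–Crick
(the intended chemistry) or any pairing scoring at/above the fidelity
threshold (misassembly prediction) — and circular products are
enumerated over orientation-preserving arrangements with at most one
copy of each fragment.  A full-design round trip (PCR → digestion →
strict ligation → compare to target up to rotation) proves a design
scarless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .core import PlasmidDesign, revcomp, rotate_to_canonical, validate_dna
from .errors import ValidationError
from .fidelity import FidelityModel, duplex_score
from .guides import CutGeometry, DEFAULT_GEOMETRY, RecognitionSite
from .primers import simulate_pcr


@dataclass
class DigestedFragment:
    """An amplicon after digestion at both termini.

    ``top_strand`` is the retained top strand (5'→3'); the left overhang
    is the protruding 5' end of the top strand, the right overhang the
    protruding 5' end of the bottom strand (both 5'→3' of the protruding
    strand).  Released oligos are the trimmed terminal single-strand
    pieces; together with the retained strands they conserve every base
    of the input amplicon.
    """

    fragment_id: str
    top_strand: str
    bottom_strand: str  # 5'->3'
    left_overhang: str
    right_overhang: str
    released_oligos: list = field(default_factory=list)
    released_left: list = field(default_factory=list)  # trimmed at the left terminus
    released_right: list = field(default_factory=list)


def _locate_terminal_window(amplicon: str, site: RecognitionSite):
    """Which terminus of the amplicon carries the site's 24-mer (or None)."""
    w = site.sequence24
    at_left = amplicon.startswith(w)
    at_right = amplicon.endswith(w)
    return at_left, at_right


def simulate_digestion(
    amplicon: str,
    left_site: Optional[RecognitionSite],
    right_site: Optional[RecognitionSite] = None,
    geometry: CutGeometry = DEFAULT_GEOMETRY,
    *,
    fragment_id: str = "amplicon",
) -> DigestedFragment:
    """Digest an amplicon at the termini carrying the given sites.

    Pass one site (found automatically at either terminus) or both.  The
    resulting overhang strings equal each site's sticky end; an amplicon
    lacking a site's 24-mer at a terminus is a design inconsistency.
    """
    amplicon = validate_dna(amplicon, context="amplicon")
    n = len(amplicon)
    if right_site is None and left_site is not None:
        at_left, at_right = _locate_terminal_window(amplicon, left_site)
        if not at_left and not at_right:
            raise ValidationError(
                f"{fragment_id}: recognition sequence {left_site.sequence24} not found "
                "at either amplicon terminus"
            )
        if at_right and not at_left:
            left_site, right_site = None, left_site

    tc, bc = geometry.top_cut, geometry.bottom_cut
    top_start, top_end = 0, n  # retained top-strand interval
    bot_start, bot_end = 0, n  # retained bottom-strand interval (top coords)
    released_left, released_right = [], []
    left_ov = right_ov = ""

    if left_site is not None:
        if not amplicon.startswith(left_site.sequence24):
            raise ValidationError(
                f"{fragment_id}: left terminus does not carry {left_site.sequence24}"
            )
        top_start = tc
        bot_start = bc
        released_left.append(amplicon[:tc])  # trimmed top 5' piece
        released_left.append(revcomp(amplicon[:bc]))  # trimmed bottom 3'-side piece
        left_ov = amplicon[tc:bc]
    if right_site is not None:
        w0 = n - geometry.window_length
        if not amplicon.endswith(right_site.sequence24):
            raise ValidationError(
                f"{fragment_id}: right terminus does not carry {right_site.sequence24}"
            )
        top_end = w0 + tc
        bot_end = w0 + bc
        released_right.append(amplicon[top_end:])
        released_right.append(revcomp(amplicon[bot_end:]))
        right_ov = revcomp(amplicon[top_end:bot_end])

    released_left = [r for r in released_left if r]
    released_right = [r for r in released_right if r]
    return DigestedFragment(
        fragment_id=fragment_id,
        top_strand=amplicon[top_start:top_end],
        bottom_strand=revcomp(amplicon[bot_start:bot_end]),
        left_overhang=left_ov,
        right_overhang=right_ov,
        released_oligos=released_left + released_right,
        released_left=released_left,
        released_right=released_right,
    )


class LigationMode(str, Enum):
    STRICT_WC = "strict_wc"
    THRESHOLD = "threshold"


@dataclass
class AssemblyProduct:
    sequence: str  # top strand; circular products given as-joined (un-rotated)
    member_ids: list
    junction_scores: list
    circular: bool = True

    @property
    def canonical(self) -> str:
        return rotate_to_canonical(self.sequence)


def _ends_compatible(right_ov: str, left_ov: str, model: FidelityModel,
                     mode: LigationMode) -> Optional[float]:
    """Score if the bottom-strand right overhang can ligate to the top-strand
    left overhang, else None."""
    if not right_ov or not left_ov or len(right_ov) != len(left_ov):
        return None
    if mode is LigationMode.STRICT_WC:
        return 12.0 if revcomp(right_ov) == left_ov else None
    score = duplex_score(left_ov, right_ov, model)
    return score if score >= model.threshold else None


def simulate_ligation(
    fragments: list,
    model: FidelityModel = None,
    mode: LigationMode = LigationMode.STRICT_WC,
) -> list:
    """Enumerate circular ligation products over the digested fragments.

    Joins fragment A's right overhang to fragment B's left overhang when
    compatible under ``mode`` (perfect Watson–Crick complementarity, or
    duplex score at/above the fidelity threshold).  Circular products use
    each fragment at most once and preserve orientation; the returned
    list is deduplicated by cycle and sorted by size descending.
    """
    if not fragments:
        raise ValidationError("need at least one digested fragment")
    model = model or FidelityModel()
    mode = LigationMode(mode)
    n = len(fragments)
    edges = {}
    for i, a in enumerate(fragments):
        for j, b in enumerate(fragments):
            score = _ends_compatible(a.right_overhang, b.left_overhang, model, mode)
            if score is not None:
                edges.setdefault(i, []).append((j, score))

    products = []
    seen_cycles = set()

    def extend(path, scores):
        last = path[-1]
        for j, score in edges.get(last, []):
            if j == path[0] and len(path) >= 1:
                key = _canonical_cycle(path)
                if key not in seen_cycles:
                    seen_cycles.add(key)
                    products.append(_build_product(path, scores + [score], fragments))
            if j not in path and j > path[0]:
                # start index is the cycle's minimum, avoiding duplicates
                extend(path + [j], scores + [score])

    for start in range(n):
        extend([start], [])
    products.sort(key=lambda p: (-len(p.sequence), p.member_ids))
    return products


def _canonical_cycle(path):
    k = path.index(min(path))
    return tuple(path[k:] + path[:k])


def _build_product(path, scores, fragments) -> AssemblyProduct:
    seq = "".join(fragments[i].top_strand for i in path)
    return AssemblyProduct(
        sequence=seq,
        member_ids=[fragments[i].fragment_id for i in path],
        junction_scores=scores,
        circular=True,
    )


@dataclass
class RoundTripResult:
    passed: bool
    n_products: int
    diffs: list = field(default_factory=list)  # (position, expected, got)
    detail: str = ""
    released_rejoin_risks: list = field(default_factory=list)


def round_trip_check(
    design: PlasmidDesign,
    primers: dict,
    model: FidelityModel = None,
    geometry: CutGeometry = DEFAULT_GEOMETRY,
) -> RoundTripResult:
    """Prove a finalized design scarless by full in-silico assembly.

    Simulates PCR of every fragment from its raw template using the
    designed primers, digests each amplicon at both termini with its
    junction sites, ligates strictly, and compares the single circular
    product to the target sequence up to rotation/reflection.  Any
    mismatch is reported base-by-base on the canonical forms.
    """
    model = model or FidelityModel()
    n = design.n_fragments
    digested = []
    for i, frag in enumerate(design.fragments):
        pair = primers[frag.id]
        product = simulate_pcr(frag.sequence, pair)
        left_site = design.junctions[(i - 1) % n].chosen_site
        right_site = design.junctions[i].chosen_site
        if left_site is None or right_site is None:
            raise ValidationError("round_trip_check requires finalized sites")
        digested.append(
            simulate_digestion(product, left_site, right_site, geometry,
                               fragment_id=frag.id)
        )

    products = simulate_ligation(digested, model, LigationMode.STRICT_WC)
    full = [p for p in products if len(p.member_ids) == n]
    if len(products) != 1 or not full:
        return RoundTripResult(
            passed=False,
            n_products=len(products),
            detail=f"expected exactly 1 circular product using all {n} fragments, "
                   f"got {len(products)} ({[p.member_ids for p in products]})",
        )
    got = full[0].canonical
    want = rotate_to_canonical(design.target_sequence)
    diffs = []
    if got != want:
        if len(got) != len(want):
            detail = f"product length {len(got)} != target length {len(want)}"
            diffs = _align_diffs(want, got)
        else:
            detail = "product differs from target"
            diffs = [(i, w, g) for i, (w, g) in enumerate(zip(want, got)) if w != g]
        return RoundTripResult(False, 1, diffs, detail)

    # a released oligo always contains its own junction's sticky end (the
    # trimmed guide-side piece) — inherent to the chemistry; flag only
    # complementarity to a DIFFERENT junction's overhang (cross-talk)
    risks = []
    for i, d in enumerate(digested):
        for side, oligos in (("left", d.released_left), ("right", d.released_right)):
            j_own = (i - 1) % n if side == "left" else i
            for oligo in oligos:
                for j, junction in enumerate(design.junctions):
                    if j == j_own or junction.chosen_site is None:
                        continue
                    sticky = junction.chosen_site.sticky_end
                    if sticky in oligo or revcomp(sticky) in oligo:
                        risks.append((d.fragment_id, oligo, sticky))
    return RoundTripResult(True, 1, [], "scarless", released_rejoin_risks=risks)


def _align_diffs(want: str, got: str, limit: int = 50) -> list:
    diffs = []
    for i in range(min(len(want), len(got))):
        if want[i] != got[i]:
            diffs.append((i, want[i], got[i]))
            if len(diffs) >= limit:
                break
    return diffs
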