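"""Primer design: binding-site sizing, Tm balancing, junction overhangs.

Each fragment is PCR-amplified with primers whose 3' binding regions
anneal at (or near) the fragment termini and whose 5' tails install the
24-bp recognition sequences chosen at the flanking junctions, so that
adjacent amplicons share exactly 24 bp of homology.  Binding regions
start at 18 bp and are resized by GC content, then the forward/reverse
lengths are jointly adjusted until their melting temperatures agree
within 1 °C.

Tm engine: nearest-neighbor thermodynamics with the unified SantaLucia
(1998) ΔH/ΔS parameter set and entropic salt correction
ΔS' = ΔS + 0.368·(N−1)·ln[Na+_eff], with divalent ions folded into an
effective monovalent concentration (von Ahsen/Owczarzy square-root
rule).  Defaults (50 mM monovalent, 50 nM primer) reproduce the common
Primer3-style calcTm parameterization.

Fragments shorter than 80 bp (linkers, small promoters) cannot host a
junction on each side; they are absorbed into the downstream neighbour's
forward primer tail across two PCR rounds (round 1 adds the linker half
nearest the neighbour, round 2 completes the linker and the junction
overhang), and the junction set is rebuilt over the merged fragment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .core import (
    JUNCTION_HOMOLOGY,
    PlasmidDesign,
    SEARCH_FLANK,
    circular_slice,
    gc_content,
    revcomp,
    validate_dna,
)
from .errors import InfeasiblePairError, ValidationError
from .guides import window_target_start

SMALL_FRAGMENT_MAX = 80  # bp; strictly below this routes to the two-round workflow

# Unified nearest-neighbor parameters (kcal/mol, cal/mol/K per stack).
_NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_INIT_GC = (0.1, -2.8)  # terminal G·C initiation
_INIT_AT = (2.3, 4.1)  # terminal A·T initiation
_R = 1.987  # cal/mol/K


@dataclass(frozen=True)
class TmParameters:
    """Solution conditions for the nearest-neighbor Tm calculation."""

    monovalent_mM: float = 50.0
    divalent_mM: float = 0.0
    dntp_mM: float = 0.0
    primer_nM: float = 50.0

    def __post_init__(self):
        if self.monovalent_mM <= 0 or self.primer_nM <= 0:
            raise ValidationError("monovalent salt and primer concentrations must be > 0")
        if self.divalent_mM < 0 or self.dntp_mM < 0:
            raise ValidationError("divalent/dNTP concentrations must be >= 0")

    @property
    def effective_monovalent_M(self) -> float:
        free_dv = max(0.0, self.divalent_mM - self.dntp_mM)
        return (self.monovalent_mM + 120.0 * math.sqrt(free_dv)) / 1000.0


def compute_tm(seq: str, params: TmParameters = TmParameters()) -> float:
    """Nearest-neighbor melting temperature (°C) of a primer binding region."""
    seq = validate_dna(seq, context="primer")
    n = len(seq)
    if not 8 <= n <= 36:
        raise ValidationError(f"Tm is defined for 8-36 nt primers, got {n}")
    dh, ds = 0.0, 0.0
    for i in range(n - 1):
        h, s = _NN[seq[i : i + 2]]
        dh += h
        ds += s
    for terminal in (seq[0], seq[-1]):
        h, s = _INIT_GC if terminal in "GC" else _INIT_AT
        dh += h
        ds += s
    ds_salt = ds + 0.368 * (n - 1) * math.log(params.effective_monovalent_M)
    ct = params.primer_nM * 1e-9
    return dh * 1000.0 / (ds_salt + _R * math.log(ct / 4.0)) - 273.15


@dataclass
class PrimerConfig:
    """Binding-site sizing and balancing knobs (conventional defaults)."""

    tm_floor: float = 58.0
    min_len: int = 15
    max_len: int = 30
    start_len: int = 18
    gc_low: float = 0.40
    gc_high: float = 0.60
    max_overhang: int = 40  # nt; longer tails get a synthesis-practicality warning
    # fallback grid when [min_len, max_len] cannot balance a pair whose two
    # termini differ sharply in composition (AT-rich vs GC-rich)
    fallback_min_len: int = 12
    fallback_max_len: int = 36
    tm_params: TmParameters = field(default_factory=TmParameters)


@dataclass
class PrimerPair:
    """Primers for one fragment: 3' binding regions + 5' junction tails."""

    fragment_id: str
    fwd_binding: str
    rev_binding: str
    fwd_overhang: str = ""
    rev_overhang: str = ""
    fwd_tm: float = float("nan")
    rev_tm: float = float("nan")
    fwd_template_start: int = 0  # template offset where fwd binding anneals
    rev_template_end: int = 0  # template offset one past the rev binding 3' base
    template_id: Optional[str] = None
    warnings: list = field(default_factory=list)

    @property
    def fwd_full(self) -> str:
        return self.fwd_overhang + self.fwd_binding

    @property
    def rev_full(self) -> str:
        return self.rev_overhang + self.rev_binding

    @property
    def delta_tm(self) -> float:
        return abs(self.fwd_tm - self.rev_tm)


@dataclass
class BindingRegion:
    sequence: str
    length: int
    tm: float
    warning: Optional[str] = None


def size_binding_site(
    template: str,
    end: str,
    config: PrimerConfig = None,
    *,
    anchor_offset: int = 0,
) -> BindingRegion:
    """Size one binding region anchored at a fragment terminus.

    ``end`` is "fwd" (anneals from the template 5' side, region read as
    top strand) or "rev" (anneals at the 3' side, region returned reverse
    complemented).  ``anchor_offset`` shifts the anchor inward when the
    recognition window reaches into the fragment past the terminus.

    Starts from the terminal 18 bp; AT-rich starts (GC < 0.40) extend
    3'-ward up to 30 bp until the Tm floor is met, GC-rich starts
    (GC > 0.60) shrink down to 15 bp while the floor still holds.
    """
    config = config or PrimerConfig()
    template = validate_dna(template, context="template")

    def region(length: int) -> str:
        if end == "fwd":
            start = anchor_offset
            seq = template[start : start + length]
        elif end == "rev":
            stop = len(template) - anchor_offset
            seq = revcomp(template[stop - length : stop])
        else:
            raise ValidationError("end must be 'fwd' or 'rev'")
        if len(seq) != length:
            raise ValidationError("fragment too short for the requested binding region")
        return seq

    length = config.start_len
    seq = region(length)
    gc = gc_content(seq)
    warning = None
    if gc > config.gc_high:
        while length > config.min_len and compute_tm(region(length - 1), config.tm_params) >= config.tm_floor:
            length -= 1
        seq = region(length)
    else:
        while compute_tm(seq, config.tm_params) < config.tm_floor and length < config.max_len:
            length += 1
            seq = region(length)
    tm = compute_tm(seq, config.tm_params)
    if tm < config.tm_floor:
        warning = (
            f"{end} binding region Tm {tm:.1f} °C below floor {config.tm_floor} °C "
            f"at maximum length {length}"
        )
    return BindingRegion(sequence=seq, length=length, tm=tm, warning=warning)


def balance_tm(
    template: str,
    config: PrimerConfig = None,
    *,
    fwd_anchor: int = 0,
    rev_anchor: int = 0,
) -> tuple:
    """Choose forward/reverse binding lengths with |ΔTm| ≤ 1 °C.

    Exhaustive search over the [min_len, max_len] length grid; among
    combinations within 1 °C it prefers ones meeting the Tm floor on both
    sides, then the smallest |ΔTm|, then lengths closest to 18/18.  When
    the standard grid cannot balance (sharply AT-rich vs GC-rich termini)
    the search widens once to the fallback grid and flags the pair;
    :class:`InfeasiblePairError` (reporting the best achievable |ΔTm|) is
    raised only when even the widened grid fails.
    """
    config = config or PrimerConfig()
    template = validate_dna(template, context="template")
    params = config.tm_params

    def fwd_region(length):
        seq = template[fwd_anchor : fwd_anchor + length]
        return seq if len(seq) == length else None

    def rev_region(length):
        stop = len(template) - rev_anchor
        if stop - length < 0:
            return None
        return revcomp(template[stop - length : stop])

    def search(min_len: int, max_len: int):
        candidates = []
        best_delta = None
        for lf in range(min_len, max_len + 1):
            f = fwd_region(lf)
            if f is None:
                continue
            tf = compute_tm(f, params)
            for lr in range(min_len, max_len + 1):
                r = rev_region(lr)
                if r is None:
                    continue
                tr = compute_tm(r, params)
                delta = abs(tf - tr)
                if best_delta is None or delta < best_delta:
                    best_delta = delta
                if delta <= 1.0:
                    floor_misses = (tf < config.tm_floor) + (tr < config.tm_floor)
                    dist = abs(lf - config.start_len) + abs(lr - config.start_len)
                    # near-equal deltas (0.25 °C buckets) tie-break toward
                    # hotter, then shorter-excursion, pairs — deterministically
                    candidates.append(
                        (floor_misses, round(delta / 0.25), -round(min(tf, tr), 2),
                         round(delta, 9), dist, lf, lr, f, r, tf, tr)
                    )
        return candidates, best_delta

    warnings = []
    candidates, best_delta = search(config.min_len, config.max_len)
    if not candidates:
        candidates, fb_delta = search(config.fallback_min_len, config.fallback_max_len)
        if not candidates:
            best = min(x for x in (best_delta, fb_delta) if x is not None)
            raise InfeasiblePairError(
                f"no binding-length combination within "
                f"[{config.fallback_min_len},{config.fallback_max_len}] achieves "
                f"|ΔTm| ≤ 1.0 °C (best {best:.2f} °C)",
                best_delta_tm=best,
            )
        warnings.append(
            f"binding lengths outside [{config.min_len},{config.max_len}] were needed "
            f"to balance Tm (standard grid best |ΔTm| {best_delta:.2f} °C)"
        )
    *_, lf, lr, f, r, tf, tr = min(candidates)
    if tf < config.tm_floor or tr < config.tm_floor:
        warnings.append(
            f"balanced pair sits below the Tm floor ({tf:.1f}/{tr:.1f} °C < {config.tm_floor})"
        )
    return f, r, tf, tr, warnings


def _amplicon_span(design: PlasmidDesign, frag_index: int) -> tuple:
    """(start, length) of a fragment's amplicon in target coordinates.

    The amplicon runs from the left junction's recognition-window start to
    the right junction's window end, so adjacent amplicons share exactly
    the 24-bp recognition sequence.
    """
    n = design.n_fragments
    total = len(design.target_sequence)
    left_j = (frag_index - 1) % n
    right_j = frag_index
    s_left = window_target_start(design, left_j)
    s_right = window_target_start(design, right_j)
    if n == 1:
        length = total + JUNCTION_HOMOLOGY
    else:
        length = (s_right - s_left) % total + JUNCTION_HOMOLOGY
    return s_left, length


def amplicon_sequence(design: PlasmidDesign, frag_index: int) -> str:
    """Top strand of the designed amplicon for one fragment."""
    start, length = _amplicon_span(design, frag_index)
    target = design.target_sequence
    total = len(target)
    if length <= total:
        return circular_slice(target, start, start + length)
    return circular_slice(target, start, start + total) + circular_slice(
        target, start, start + (length - total)
    )


def _end_geometry(design: PlasmidDesign, frag_index: int) -> tuple:
    """(fwd_anchor, left_overhang_len, rev_anchor, right_overhang_len).

    With the left junction window at offset w_l in its 80-nt search space
    (the fragment boundary at 40), the amplicon start sits 40 − w_l bases
    before the fragment start: the forward primer carries that many tail
    bases, or — when w_l > 40 — anneals w_l − 40 bases inside the
    fragment.  Symmetrically the right window at offset w_r ends
    w_r − 16 bases past the fragment end (reverse tail), or truncates
    16 − w_r bases when w_r < 16.
    """
    n = design.n_fragments
    w_l = design.junctions[(frag_index - 1) % n].chosen_site.window_offset
    w_r = design.junctions[frag_index].chosen_site.window_offset
    fwd_anchor = max(0, w_l - SEARCH_FLANK)
    left_ov = max(0, SEARCH_FLANK - w_l)
    right_trunc = max(0, (SEARCH_FLANK - JUNCTION_HOMOLOGY) - w_r)  # 16 - w_r
    right_ov = max(0, w_r - (SEARCH_FLANK - JUNCTION_HOMOLOGY))
    return fwd_anchor, left_ov, right_trunc, right_ov


def attach_overhangs(pair: PrimerPair, design: PlasmidDesign, frag_index: int,
                     config: PrimerConfig = None) -> PrimerPair:
    """Add 5' tails so the amplicon carries both full 24-bp junction windows.

    The tail length at each end is the part of the amplicon span that lies
    outside the raw fragment; with the window centered on the boundary
    (offset 28) each amplicon adds 12 nt per end, and a window reaching
    further into the neighbouring fragment requires proportionally longer
    tails.
    """
    config = config or PrimerConfig()
    frag = design.fragments[frag_index]
    f_start = design.fragment_start(frag.id)
    f_end = f_start + len(frag)
    _, left_ov, _, right_ov = _end_geometry(design, frag_index)

    pair.fwd_overhang = circular_slice(
        design.target_sequence, f_start - left_ov + len(design), f_start + len(design)
    ) if left_ov else ""
    pair.rev_overhang = revcomp(
        circular_slice(design.target_sequence, f_end, f_end + right_ov)
    ) if right_ov else ""
    for name, ov in (("forward", pair.fwd_overhang), ("reverse", pair.rev_overhang)):
        if len(ov) > config.max_overhang:
            pair.warnings.append(
                f"{name} overhang of {len(ov)} nt exceeds {config.max_overhang} nt "
                "(synthesis practicality)"
            )
    return pair


def design_fragment_pair(design: PlasmidDesign, frag_index: int,
                         config: PrimerConfig = None) -> PrimerPair:
    """Full primer pair for one fragment of a site-finalized design."""
    config = config or PrimerConfig()
    frag = design.fragments[frag_index]
    fwd_anchor, _, rev_anchor, _ = _end_geometry(design, frag_index)

    f, r, tf, tr, warnings = balance_tm(
        frag.sequence, config, fwd_anchor=fwd_anchor, rev_anchor=rev_anchor
    )
    pair = PrimerPair(
        fragment_id=frag.id,
        fwd_binding=f,
        rev_binding=r,
        fwd_tm=tf,
        rev_tm=tr,
        fwd_template_start=fwd_anchor,
        rev_template_end=len(frag) - rev_anchor,
        template_id=frag.template_id or frag.id,
        warnings=list(warnings),
    )
    return attach_overhangs(pair, design, frag_index, config)


def design_primers(design: PlasmidDesign, config: PrimerConfig = None) -> dict:
    """Primer pairs for every fragment; requires finalized recognition sites."""
    config = config or PrimerConfig()
    return {
        frag.id: design_fragment_pair(design, i, config)
        for i, frag in enumerate(design.fragments)
    }


def simulate_pcr(template: str, pair: PrimerPair) -> str:
    """Exact-string PCR product: primers incorporated verbatim, template
    copied between the binding sites (no polymerase error model)."""
    template = validate_dna(template, context="template")
    a = pair.fwd_template_start + len(pair.fwd_binding)
    e = pair.rev_template_end - len(pair.rev_binding)
    if a > pair.rev_template_end or e < pair.fwd_template_start:
        raise ValidationError("primer binding sites overlap or are out of order")
    return pair.fwd_full + template[a:e] + revcomp(pair.rev_full)


# ---------------------------------------------------------------------------
# small-fragment (<80 bp) two-round workflow


@dataclass
class MergeRecord:
    linker_id: str
    host_id: str
    merged_id: str
    linker_sequence: str


@dataclass
class SmallFragmentPlan:
    """Two-round extended-primer plan absorbing a short linker."""

    merge: MergeRecord
    round1: PrimerPair  # template: the host fragment
    round2: PrimerPair  # template: the round-1 product


def absorb_small_fragments(design: PlasmidDesign, threshold: int = SMALL_FRAGMENT_MAX):
    """Merge every fragment shorter than ``threshold`` into its downstream
    neighbour, rebuilding the junction set over the merged fragments.

    Returns (new_design, merge_records).  The merged fragment's PCR
    template remains the host fragment; the linker arrives via primer
    tails (see :func:`design_small_fragment`).
    """
    from .core import Fragment

    n = design.n_fragments
    if n < 2:
        return design, []
    small = [i for i, f in enumerate(design.fragments) if len(f) < threshold]
    if not small:
        return design, []
    consumed = set()
    merges = []
    new_fragments = []
    for i, frag in enumerate(design.fragments):
        if i in consumed:
            continue
        if len(frag) < threshold:
            host = design.fragments[(i + 1) % n]
            if len(host) < threshold:
                raise ValidationError(
                    f"adjacent fragments {frag.id} and {host.id} are both shorter than "
                    f"{threshold} bp; cannot absorb a linker into another linker"
                )
            merged_id = f"{frag.id}+{host.id}"
            merges.append(
                MergeRecord(
                    linker_id=frag.id,
                    host_id=host.id,
                    merged_id=merged_id,
                    linker_sequence=frag.sequence,
                )
            )
            new_fragments.append(
                Fragment(
                    id=merged_id,
                    sequence=frag.sequence + host.sequence,
                    role=host.role,
                    template_id=host.template_id or host.id,
                    order_index=0,  # reassigned below
                )
            )
            consumed.add(i)
            consumed.add((i + 1) % n)
        else:
            new_fragments.append(
                Fragment(
                    id=frag.id,
                    sequence=frag.sequence,
                    role=frag.role,
                    template_id=frag.template_id,
                    order_index=0,
                    features=frag.features,
                )
            )
    # wrap-around: a trailing linker merged into fragment 0 removes it from the front
    if 0 in consumed and new_fragments and not new_fragments[0].id.startswith(
        design.fragments[0].id
    ):
        pass
    for k, f in enumerate(new_fragments):
        f.order_index = k
    merged = PlasmidDesign.from_fragments(design.name, new_fragments)
    return merged, merges


def design_small_fragment(
    merge: MergeRecord,
    merged_pair: PrimerPair,
    host_sequence: str,
    config: PrimerConfig = None,
) -> SmallFragmentPlan:
    """Split a merged fragment's long forward tail across two PCR rounds.

    The final amplicon's 5' region is [junction overhang][linker][host...].
    Round 1 amplifies the host with a tail carrying the linker half nearest
    the host; round 2 uses the round-1 product as template and adds the
    remaining linker half plus the junction overhang ("the PCR from the
    first round is used as template for the second PCR").
    """
    config = config or PrimerConfig()
    linker = merge.linker_sequence
    if len(linker) >= SMALL_FRAGMENT_MAX:
        raise ValidationError(
            f"linker {merge.linker_id} is {len(linker)} bp; the two-round workflow "
            f"only applies below {SMALL_FRAGMENT_MAX} bp"
        )
    # portion of the merged-template binding region that lies in the linker
    a = merged_pair.fwd_template_start
    in_linker = max(0, len(linker) - a)
    tail_total = merged_pair.fwd_overhang + linker[a : a + in_linker]
    half = (len(tail_total) + 1) // 2
    tail_r1, tail_r2 = tail_total[half:], tail_total[:half]

    host_anchor = max(0, a - len(linker))
    host_binding = host_sequence[host_anchor : host_anchor + max(
        len(merged_pair.fwd_binding) - in_linker, config.min_len
    )]
    round1 = PrimerPair(
        fragment_id=f"{merge.merged_id}:round1",
        fwd_binding=host_binding,
        rev_binding=merged_pair.rev_binding,
        fwd_overhang=tail_r1,
        rev_overhang=merged_pair.rev_overhang,
        fwd_tm=compute_tm(host_binding, config.tm_params),
        rev_tm=merged_pair.rev_tm,
        fwd_template_start=host_anchor,
        rev_template_end=len(host_sequence) - (
            len(merge.linker_sequence + host_sequence) - merged_pair.rev_template_end
        ),
        template_id=merge.host_id,
    )
    product1 = simulate_pcr(host_sequence, round1)
    # round 2 re-amplifies the full round-1 product (whose 3' end already
    # carries the right overhang) while the forward tail completes the linker
    r2_fwd_len = min(config.start_len, len(tail_r1) + len(host_binding))
    r2_rev_len = min(config.start_len, len(product1))
    round2 = PrimerPair(
        fragment_id=f"{merge.merged_id}:round2",
        fwd_binding=product1[:r2_fwd_len],
        rev_binding=revcomp(product1[-r2_rev_len:]),
        fwd_overhang=tail_r2,
        rev_overhang="",
        fwd_tm=float("nan"),
        rev_tm=float("nan"),
        fwd_template_start=0,
        rev_template_end=len(product1),
        template_id=f"{merge.merged_id}:round1",
    )
    return SmallFragmentPlan(merge=merge, round1=round1, round2=round2)


def primer_order_table(pairs: dict) -> list:
    """Oligo-order rows (name, sequence, binding length, Tm, overhang length)."""
    rows = []
    for fid, pair in pairs.items():
        rows.append(
            {
                "name": f"{fid}_F",
                "sequence": pair.fwd_full,
                "binding_length": len(pair.fwd_binding),
                "tm": round(pair.fwd_tm, 2),
                "overhang_length": len(pair.fwd_overhang),
            }
        )
        rows.append(
            {
                "name": f"{fid}_R",
                "sequence": pair.rev_full,
                "binding_length": len(pair.rev_binding),
                "tm": round(pair.rev_tm, 2),
                "overhang_length": len(pair.rev_overhang),
            }
        )
    return rows
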