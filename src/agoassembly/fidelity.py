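"""Sticky-end ligation fidelity model.

Each junction contributes a cognate pair of 12-nt 5' overhangs (a sticky
end and its exact reverse complement).  A high-fidelity assembly needs
the whole set to be orthogonal: no palindromic end (self-ligation), no
duplicated cognate pair, and every *non-cognate* pairing annealing weakly
under the ligase mismatch profile.  The pairing score is a per-position,
ungapped, antiparallel sum over a 4x4 base-pairing weight table in which
Watson-Crick pairs score 1 and mismatches score in [0, 1); a cognate pair
scores exactly 12.

The shipped default weight table is a synthetic stand-in with the
qualitative shape of a thermostable ligase mismatch profile (G·T wobble
tolerated at 0.3, all other mismatches 0.05); replace it with a measured
profile via ``FidelityModel.from_tsv``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from importlib.resources import files
from pathlib import Path
from typing import Optional

from .core import revcomp, validate_dna
from .errors import ValidationError

STICKY_LEN = 12

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


class Side(str, Enum):
    UPSTREAM_END = "upstream_end"
    DOWNSTREAM_END = "downstream_end"


@dataclass(frozen=True)
class StickyEnd:
    """A 12-nt 5' overhang (protruding strand, 5'->3')."""

    sequence12: str
    junction_index: int = -1
    side: Side = Side.DOWNSTREAM_END

    def __post_init__(self):
        seq = validate_dna(self.sequence12, context="sticky end")
        if len(seq) != STICKY_LEN:
            raise ValidationError(f"sticky end must be {STICKY_LEN} nt, got {len(seq)}")
        object.__setattr__(self, "sequence12", seq)


def _default_table() -> dict:
    table = {}
    for a in "ACGT":
        for b in "ACGT":
            if (a, b) in _WC:
                table[(a, b)] = 1.0
            elif {a, b} == {"G", "T"}:
                table[(a, b)] = 0.3
            else:
                table[(a, b)] = 0.05
    return table


@dataclass
class FidelityModel:
    """4x4 pairing-weight table + acceptance threshold for non-cognate scores."""

    table: dict = field(default_factory=_default_table)
    threshold: float = 8.0
    table_source: str = "synthetic default (WC=1, G.T=0.3, other=0.05)"

    def __post_init__(self):
        for a in "ACGT":
            for b in "ACGT":
                if (a, b) not in self.table:
                    raise ValidationError(f"fidelity table missing pair {a}-{b}")
                w = self.table[(a, b)]
                if (a, b) in _WC:
                    if w != 1.0:
                        raise ValidationError("Watson-Crick pairs must score exactly 1.0")
                elif not 0.0 <= w < 1.0:
                    raise ValidationError(f"mismatch weight {a}-{b} must be in [0,1)")

    def match_score(self, a: str, b: str) -> float:
        return self.table[(a, b)]

    @classmethod
    def from_tsv(cls, path, threshold: float = 8.0) -> "FidelityModel":
        """Load a 16-row TSV (base_a, base_b, weight)."""
        table = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip() or line.startswith("#") or line.lower().startswith("base_a"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}: bad fidelity row (line {lineno})")
            table[(parts[0].upper(), parts[1].upper())] = float(parts[2])
        return cls(table=table, threshold=threshold, table_source=str(path))

    @classmethod
    def packaged_default(cls, threshold: float = 8.0) -> "FidelityModel":
        path = files("agoassembly").joinpath("data/hifi_taq_mismatch_synthetic.tsv")
        return cls.from_tsv(path, threshold=threshold)


def is_palindromic(end) -> bool:
    """True iff the overhang equals its own reverse complement.

    A palindromic 5' overhang anneals with an identical copy of itself,
    allowing a fragment end to self-ligate; such ends are banned.
    """
    seq = end.sequence12 if isinstance(end, StickyEnd) else validate_dna(end)
    return seq == revcomp(seq)


def duplex_score(end_a, end_b, model: FidelityModel = None) -> float:
    """Antiparallel pairing score of two overhangs: Σ_i w(a[i], b[11-i]).

    Symmetric in its arguments; 12.0 for a cognate (exact reverse
    complement) pair, down to near 0 for unrelated ends.
    """
    model = model or FidelityModel()
    a = end_a.sequence12 if isinstance(end_a, StickyEnd) else validate_dna(end_a)
    b = end_b.sequence12 if isinstance(end_b, StickyEnd) else validate_dna(end_b)
    if len(a) != STICKY_LEN or len(b) != STICKY_LEN:
        raise ValidationError("duplex_score expects two 12-nt ends")
    return sum(model.match_score(a[i], b[STICKY_LEN - 1 - i]) for i in range(STICKY_LEN))


@dataclass
class OrthogonalityVerdict:
    passed: bool
    reason: Optional[str]
    max_noncognate_score: float
    worst_pair: Optional[tuple]  # (seq_a, seq_b) achieving the max


def orthogonality_check(sticky_ends: list, model: FidelityModel = None) -> OrthogonalityVerdict:
    """Verdict on a junction set's sticky ends (one top-strand 12-mer each).

    Fails if any end is palindromic, two junctions share a cognate pair
    (equal ends or an end equal to another's complement), or any
    non-cognate duplex scores at/above the model threshold.
    """
    model = model or FidelityModel()
    seqs = [e.sequence12 if isinstance(e, StickyEnd) else validate_dna(e) for e in sticky_ends]
    for s in seqs:
        if is_palindromic(s):
            return OrthogonalityVerdict(False, f"palindromic sticky end {s}", 12.0, (s, s))
    # each junction contributes the cognate pair {s, revcomp(s)}
    pairs = [frozenset((s, revcomp(s))) for s in seqs]
    if len(set(pairs)) != len(pairs):
        dup = next(p for p in pairs if pairs.count(p) > 1)
        s = sorted(dup)[0]
        return OrthogonalityVerdict(False, f"duplicated cognate pair ({s})", 12.0, (s, s))
    ends = []
    for j, s in enumerate(seqs):
        ends.append((j, s))
        ends.append((j, revcomp(s)))
    worst, worst_pair = 0.0, None
    for i in range(len(ends)):
        for k in range(i, len(ends)):
            ja, a = ends[i]
            jb, b = ends[k]
            if ja == jb and a != b:
                continue  # the junction's own cognate pairing
            score = duplex_score(a, b, model)
            if score > worst:
                worst, worst_pair = score, (a, b)
    if worst >= model.threshold:
        return OrthogonalityVerdict(
            False, f"non-cognate duplex score {worst:.2f} >= threshold {model.threshold}",
            worst, worst_pair,
        )
    return OrthogonalityVerdict(True, None, worst, worst_pair)
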