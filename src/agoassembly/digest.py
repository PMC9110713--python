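"""Verification-digest planning and band matching.

After assembly, a plasmid is verified by restriction digestion and
capillary electrophoresis.  This module scans a circular sequence for
enzyme recognition sites (IUPAC-aware, both strands), predicts band
sizes, and selects single/double digests whose bands are well separated:
smallest band ≥ 100 bp, largest ≤ 9500 bp, and adjacent bands differing
by at least A × band size where A = 0.1 is the sizing accuracy of the
electrophoresis instrument.  It also intersects accepted enzyme
combinations across a batch of plasmids and matches predicted to
observed band lists.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from importlib.resources import files
from itertools import combinations
from pathlib import Path
from typing import Optional

from .core import revcomp, validate_dna
from .errors import ValidationError

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_IUPAC_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _iupac_regex(site: str) -> str:
    return "".join(c if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]" for c in site)


def _iupac_revcomp(site: str) -> str:
    return site.translate(_IUPAC_COMP)[::-1]


@dataclass(frozen=True)
class Enzyme:
    """One restriction enzyme: IUPAC site + top/bottom cut offsets.

    ``cut_top`` is the number of bases 5' of the top-strand cut within the
    site; ``cut_bottom`` likewise from the bottom strand's own 5' side.
    """

    name: str
    site: str
    cut_top: int
    cut_bottom: int

    def __post_init__(self):
        up = self.site.upper()
        bad = set(up) - set(IUPAC)
        if bad:
            raise ValidationError(f"enzyme {self.name}: invalid IUPAC code(s) {sorted(bad)}")
        object.__setattr__(self, "site", up)
        if not 0 <= self.cut_top <= len(up) or not 0 <= self.cut_bottom <= len(up):
            raise ValidationError(f"enzyme {self.name}: cut offsets outside the site")

    @property
    def is_palindromic(self) -> bool:
        return self.site == _iupac_revcomp(self.site)


class EnzymeTable:
    """Named collection of enzymes, loadable from a replaceable TSV."""

    def __init__(self, enzymes):
        self._enzymes = {}
        for e in enzymes:
            if e.name in self._enzymes:
                raise ValidationError(f"duplicate enzyme name {e.name}")
            self._enzymes[e.name] = e

    def __getitem__(self, name: str) -> Enzyme:
        try:
            return self._enzymes[name]
        except KeyError:
            raise KeyError(f"unknown enzyme {name!r}; known: {sorted(self._enzymes)}")

    def __contains__(self, name) -> bool:
        return name in self._enzymes

    def __iter__(self):
        return iter(self._enzymes.values())

    def __len__(self):
        return len(self._enzymes)

    @property
    def names(self) -> list:
        return sorted(self._enzymes)

    @classmethod
    def from_tsv(cls, path) -> "EnzymeTable":
        enzymes = []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip() or line.startswith("#") or line.lower().startswith("name\t"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ValidationError(f"{path}: bad enzyme row (line {lineno})")
            enzymes.append(Enzyme(parts[0], parts[1], int(parts[2]), int(parts[3])))
        return cls(enzymes)

    @classmethod
    def packaged_default(cls) -> "EnzymeTable":
        """~30 common 6/8-cutters shipped as a replaceable TSV."""
        return cls.from_tsv(files("agoassembly").joinpath("data/enzymes.tsv"))


class Rejection(str, Enum):
    TOO_SMALL = "too_small"
    TOO_LARGE = "too_large"
    TOO_CLOSE = "too_close"
    NO_CUT = "no_cut"


@dataclass
class SeparationCriteria:
    """Band-separation acceptance rules for the verification digest."""

    min_band: int = 100
    max_band: int = 9500
    accuracy_A: float = 0.1
    compare_to_larger: bool = True  # gap tested against the larger adjacent band

    def __post_init__(self):
        if not 0 < self.min_band < self.max_band:
            raise ValidationError("need 0 < min_band < max_band")
        if not 0.0 < self.accuracy_A < 1.0:
            raise ValidationError("accuracy_A must be in (0, 1)")


@dataclass
class DigestPlan:
    plasmid: str
    enzymes: tuple
    predicted_bands: list
    accepted: bool
    rejection_reason: Optional[Rejection] = None
    min_gap_ratio: float = float("inf")


from functools import lru_cache


@lru_cache(maxsize=8192)
def cut_positions(circular_seq: str, enzyme: Enzyme) -> tuple:
    """Sorted top-strand cut coordinates of one enzyme on a circular sequence.

    Sites are located on both strands (IUPAC-expanded) across the origin;
    for a bottom-strand-only site the top-strand cut coordinate follows
    from the enzyme's bottom cut offset.  Each duplex site yields exactly
    one cleavage coordinate.  Cached: digest-plan selection re-digests the
    same plasmid with every enzyme pair.
    """
    seq = validate_dna(circular_seq, context="plasmid")
    n = len(seq)
    if n == 0:
        raise ValidationError("empty plasmid sequence")
    m = len(enzyme.site)
    doubled = seq + seq[: m - 1] if m > 1 else seq
    cuts = set()
    fwd = re.compile(_iupac_regex(enzyme.site))
    fwd_positions = set()
    for i in range(len(doubled) - m + 1):
        if fwd.match(doubled, i) and i < n:
            fwd_positions.add(i)
            cuts.add((i + enzyme.cut_top) % n)
    rev = re.compile(_iupac_regex(_iupac_revcomp(enzyme.site)))
    for i in range(len(doubled) - m + 1):
        # one duplex site = one cleavage event: a position already matched on
        # the top strand (palindromic site) is the same site, not a second cut
        if i < n and i not in fwd_positions and rev.match(doubled, i):
            cuts.add((i + m - enzyme.cut_bottom) % n)
    return tuple(sorted(cuts))


def digest(circular_seq: str, enzyme_names, table: EnzymeTable = None) -> list:
    """Predicted band sizes (sorted ascending) of a circular digest.

    One cut linearizes (single full-length band); no cut returns an empty
    list.  Band sizes always sum to the plasmid length.
    """
    table = table or EnzymeTable.packaged_default()
    if isinstance(enzyme_names, str):
        enzyme_names = [enzyme_names]
    seq = validate_dna(circular_seq, context="plasmid")
    n = len(seq)
    cuts = set()
    for name in enzyme_names:
        cuts.update(cut_positions(seq, table[name]))
    if not cuts:
        return []
    ordered = sorted(cuts)
    bands = [
        (ordered[(i + 1) % len(ordered)] - ordered[i]) % n or n
        for i in range(len(ordered))
    ]
    bands.sort()
    assert sum(bands) == n, "digest conservation violated"
    return bands


def evaluate_bands(bands: list, criteria: SeparationCriteria = None):
    """(accepted, rejection_reason, min_gap_ratio) for one band list."""
    criteria = criteria or SeparationCriteria()
    if not bands:
        return False, Rejection.NO_CUT, float("inf")
    ordered = sorted(bands)
    if ordered[0] < criteria.min_band:
        return False, Rejection.TOO_SMALL, float("inf")
    if ordered[-1] > criteria.max_band:
        return False, Rejection.TOO_LARGE, float("inf")
    min_ratio = float("inf")
    for a, b in zip(ordered, ordered[1:]):
        ref = b if criteria.compare_to_larger else a
        gap = b - a
        if gap < criteria.accuracy_A * ref:
            return False, Rejection.TOO_CLOSE, gap / ref
        min_ratio = min(min_ratio, gap / ref)
    return True, None, min_ratio


def select_combinations(
    circular_seq: str,
    table: EnzymeTable = None,
    criteria: SeparationCriteria = None,
    *,
    plasmid_name: str = "plasmid",
    max_enzymes: int = 2,
) -> list:
    """Ranked accepted digest plans over all single and double digests.

    Ranking: more bands first (more informative pattern), ties broken by
    the larger minimum adjacent-gap ratio, then by enzyme names.  An empty
    result is a valid outcome.
    """
    table = table or EnzymeTable.packaged_default()
    criteria = criteria or SeparationCriteria()
    seq = validate_dna(circular_seq, context="plasmid")
    plans = []
    combos = [(n,) for n in table.names]
    if max_enzymes >= 2:
        combos += [tuple(sorted(c)) for c in combinations(table.names, 2)]
    for combo in combos:
        bands = digest(seq, list(combo), table)
        accepted, reason, ratio = evaluate_bands(bands, criteria)
        plans.append(
            DigestPlan(
                plasmid=plasmid_name,
                enzymes=combo,
                predicted_bands=bands,
                accepted=accepted,
                rejection_reason=reason,
                min_gap_ratio=ratio,
            )
        )
    accepted_plans = [p for p in plans if p.accepted]
    accepted_plans.sort(key=lambda p: (-len(p.predicted_bands), -p.min_gap_ratio, p.enzymes))
    return accepted_plans


def common_enzymes(
    plasmids: dict,
    table: EnzymeTable = None,
    criteria: SeparationCriteria = None,
    max_enzymes: int = 2,
):
    """Enzyme combinations accepted for EVERY plasmid of a batch.

    ``plasmids`` maps name -> circular sequence.  Returns (common
    combinations sorted, per-plasmid accepted plans) so callers still see
    per-plasmid fallbacks when the intersection is empty.
    """
    if not plasmids:
        raise ValidationError("need at least one plasmid")
    table = table or EnzymeTable.packaged_default()
    per_plasmid = {
        name: select_combinations(seq, table, criteria, plasmid_name=name,
                                  max_enzymes=max_enzymes)
        for name, seq in plasmids.items()
    }
    sets = [frozenset(p.enzymes for p in plans) for plans in per_plasmid.values()]
    common = set.intersection(*(set(s) for s in sets)) if sets else set()
    return sorted(common), per_plasmid


@dataclass
class BandMatch:
    passed: bool
    pairs: list = field(default_factory=list)  # (predicted, observed)
    unmatched_predicted: list = field(default_factory=list)
    unexplained_observed: list = field(default_factory=list)


def match_bands(
    predicted: list,
    observed: list,
    tolerance: float = 0.1,
    noise_floor: float = 50.0,
) -> BandMatch:
    """Greedy one-to-one pairing of predicted vs observed band sizes.

    Walking both lists in ascending order, each predicted band takes the
    smallest unused observed band within ``tolerance × predicted``.  The
    verdict passes iff every predicted band is matched and every leftover
    observed band sits below the noise floor.
    """
    if not 0.0 < tolerance < 1.0:
        raise ValidationError("tolerance must be in (0, 1)")
    pred = sorted(predicted)
    obs = sorted(observed)
    used = [False] * len(obs)
    pairs, unmatched = [], []
    for p in pred:
        hit = None
        for i, o in enumerate(obs):
            if not used[i] and abs(o - p) <= tolerance * p:
                hit = i
                break
        if hit is None:
            unmatched.append(p)
        else:
            used[hit] = True
            pairs.append((p, obs[hit]))
    unexplained = [o for i, o in enumerate(obs) if not used[i] and o >= noise_floor]
    return BandMatch(
        passed=not unmatched and not unexplained,
        pairs=pairs,
        unmatched_predicted=unmatched,
        unexplained_observed=unexplained,
    )


def read_observed_bands(path) -> list:
    """Sizes (bp) from a Fragment-Analyzer-style CSV (well, size_bp, RFU)."""
    import pandas as pd

    df = pd.read_csv(path)
    col = next((c for c in df.columns if c.lower() in {"size_bp", "size", "bp"}), None)
    if col is None:
        raise ValidationError(f"{path}: no size column (expected size_bp)")
    return sorted(float(x) for x in df[col].dropna())
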