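"""Sequence data model and elementary utilities.

A plasmid design is an ordered list of abutting DNA fragments whose
concatenation is the circular target sequence.  Every adjacent fragment
pair (including the wrap-around pair) defines a *junction*; each junction
carries an 80-nt guide search space built from 40 nt on either side of
the fragment boundary.  Coordinates are 0-based, half-open, on the top
strand; circular positions are reduced modulo the plasmid length.

Fragments are given WITHOUT the shared 24-bp junction overlaps: those are
installed later by primer overhang design, so raw fragments abut exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

from .errors import FormatError, ValidationError

SEARCH_FLANK = 40  #: nt taken from each side of a fragment boundary
SEARCH_SPACE_LEN = 2 * SEARCH_FLANK
JUNCTION_HOMOLOGY = 24  #: bp of recognition sequence shared by adjacent amplicons

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")


def validate_dna(seq: str, *, context: str = "sequence") -> str:
    """Uppercase ``seq`` and reject anything outside the ACGT alphabet.

    Ambiguity codes and U are refused: this is a DNA-only tool and every
    downstream rule (guides, sticky ends, Tm) assumes a concrete base.
    """
    if not isinstance(seq, str):
        raise ValidationError(f"{context}: expected a string, got {type(seq).__name__}")
    up = seq.upper()
    bad = set(up) - _VALID
    if bad:
        raise ValidationError(
            f"{context}: invalid characters {sorted(bad)} (alphabet is ACGT; "
            "ambiguity codes and U are rejected)"
        )
    return up


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (involution: revcomp∘revcomp = id)."""
    up = validate_dna(seq)
    return up.translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    """Fraction of G+C bases, in [0, 1]. Empty input is an error."""
    up = validate_dna(seq)
    if not up:
        raise ValidationError("gc_content: empty sequence")
    return (up.count("G") + up.count("C")) / len(up)


def rotate_to_canonical(circular_seq: str) -> str:
    """Canonical form of a circular double-stranded sequence.

    Returns the lexicographically smallest string among all rotations of
    the sequence and all rotations of its reverse complement, so two
    circles are equal (up to rotation and strand flip) iff their canonical
    forms are equal strings.
    """
    up = validate_dna(circular_seq)
    if not up:
        raise ValidationError("rotate_to_canonical: empty sequence")
    best = None
    for s in (up, revcomp(up)):
        doubled = s + s
        n = len(s)
        for i in range(n):
            rot = doubled[i : i + n]
            if best is None or rot < best:
                best = rot
    return best


def circular_slice(seq: str, start: int, end: int) -> str:
    """Top-strand slice of a circular sequence; ``start``/``end`` are taken
    modulo the length and the slice may wrap the origin. ``end - start`` is
    the slice length and must be in [0, len(seq)]."""
    n = len(seq)
    length = end - start
    if length < 0 or length > n:
        raise ValidationError(f"circular_slice: bad span {start}..{end} on length {n}")
    s = start % n
    if s + length <= n:
        return seq[s : s + length]
    return seq[s:] + seq[: s + length - n]


class Role(str, Enum):
    BACKBONE = "backbone"
    INSERT = "insert"
    LINKER = "linker"


@dataclass
class Fragment:
    """One linear DNA part of the assembly, in final plasmid orientation."""

    id: str
    sequence: str
    role: Role = Role.INSERT
    template_id: Optional[str] = None
    order_index: int = 0
    features: list = field(default_factory=list)  # (type, start, end, label)

    def __post_init__(self):
        if not self.id:
            raise ValidationError("Fragment id must be non-empty")
        self.sequence = validate_dna(self.sequence, context=f"fragment {self.id}")
        if len(self.sequence) < 1:
            raise ValidationError(f"fragment {self.id}: empty sequence")
        if not isinstance(self.role, Role):
            self.role = Role(self.role)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        return gc_content(self.sequence)


@dataclass
class Junction:
    """Boundary between two adjacent fragments, with its guide search space."""

    index: int
    upstream_fragment_id: str
    downstream_fragment_id: str
    search_space: Optional[str]  # None until both neighbours are >= 40 bp
    search_space_origin: int  # 0-based coord of search_space start in target
    boundary: int  # 0-based coord of the fragment boundary in target
    chosen_site: Optional[object] = None  # guides.RecognitionSite once selected


@dataclass
class PlasmidDesign:
    """Ordered fragments plus the circular target sequence they spell."""

    name: str
    fragments: list[Fragment]
    target_sequence: str
    junctions: list[Junction]

    def __post_init__(self):
        ids = [f.id for f in self.fragments]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate fragment id(s): {dupes}")
        order = sorted(f.order_index for f in self.fragments)
        if order != list(range(len(self.fragments))):
            raise ValidationError(
                "fragment order_index values must be a contiguous 0..n-1 permutation"
            )

    def __len__(self) -> int:
        return len(self.target_sequence)

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    def fragment(self, fragment_id: str) -> Fragment:
        for f in self.fragments:
            if f.id == fragment_id:
                return f
        raise KeyError(fragment_id)

    def fragment_start(self, fragment_id: str) -> int:
        """Target coordinate where a fragment's raw sequence begins."""
        pos = 0
        for f in self.fragments:
            if f.id == fragment_id:
                return pos
            pos += len(f)
        raise KeyError(fragment_id)

    def feature_table(self) -> list[tuple]:
        """All annotated features as (fragment_id, type, start, end, label)."""
        rows = []
        for f in self.fragments:
            for ftype, start, end, label in f.features:
                rows.append((f.id, ftype, start, end, label))
        return rows

    @classmethod
    def from_fragments(cls, name: str, fragments: Iterable[Fragment]) -> "PlasmidDesign":
        frags = sorted(fragments, key=lambda f: f.order_index)
        target = "".join(f.sequence for f in frags)
        design = cls(name=name, fragments=frags, target_sequence=target, junctions=[])
        design.junctions = _build_junctions(design)
        return design

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "fragments": [
                {
                    "id": f.id,
                    "sequence": f.sequence,
                    "role": f.role.value,
                    "template_id": f.template_id,
                    "order_index": f.order_index,
                    "features": f.features,
                }
                for f in self.fragments
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlasmidDesign":
        frags = [
            Fragment(
                id=fd["id"],
                sequence=fd["sequence"],
                role=Role(fd.get("role", "insert")),
                template_id=fd.get("template_id"),
                order_index=fd["order_index"],
                features=[tuple(x) for x in fd.get("features", [])],
            )
            for fd in d["fragments"]
        ]
        return cls.from_fragments(d["name"], frags)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path) -> "PlasmidDesign":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _build_junctions(design: PlasmidDesign) -> list[Junction]:
    n = design.n_fragments
    target = design.target_sequence
    total = len(target)
    junctions = []
    pos = 0
    for i, frag in enumerate(design.fragments):
        pos += len(frag)
        nxt = design.fragments[(i + 1) % n]
        boundary = pos % total
        if len(frag) >= SEARCH_FLANK and len(nxt) >= SEARCH_FLANK and total >= SEARCH_SPACE_LEN:
            origin = (boundary - SEARCH_FLANK) % total
            space = circular_slice(target, origin, origin + SEARCH_SPACE_LEN)
        elif frag.role is Role.LINKER or nxt.role is Role.LINKER:
            # short linkers are absorbed by the small-fragment primer
            # workflow before guide design; leave the space unset
            origin = (boundary - SEARCH_FLANK) % total
            space = None
        else:
            short = frag if len(frag) < SEARCH_FLANK else nxt
            raise ValidationError(
                f"fragment {short.id} is shorter than {SEARCH_FLANK} bp and is not a "
                "linker; cannot build a guide search space at its junction"
            )
        junctions.append(
            Junction(
                index=i,
                upstream_fragment_id=frag.id,
                downstream_fragment_id=nxt.id,
                search_space=space,
                search_space_origin=origin,
                boundary=boundary,
            )
        )
    return junctions


# ---------------------------------------------------------------------------
# file ingestion

MANIFEST_COLUMNS = ("fragment_id", "file", "role", "order_index", "template_id")


def _read_manifest(manifest_path) -> list[dict]:
    rows = []
    path = Path(manifest_path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty manifest")
    header = lines[0].rstrip("\n").split("\t")
    missing = [c for c in MANIFEST_COLUMNS[:4] if c not in header]
    if missing:
        raise FormatError(f"{path}: manifest missing column(s) {missing} (line 1)")
    idx = {c: header.index(c) for c in header}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        try:
            row = {
                "fragment_id": parts[idx["fragment_id"]],
                "file": parts[idx["file"]],
                "role": parts[idx["role"]] or "insert",
                "order_index": int(parts[idx["order_index"]]),
                "template_id": (
                    parts[idx["template_id"]]
                    if "template_id" in idx and len(parts) > idx["template_id"] and parts[idx["template_id"]]
                    else None
                ),
            }
        except (IndexError, ValueError) as exc:
            raise FormatError(f"{path}: bad manifest row (line {lineno}): {exc}") from exc
        rows.append(row)
    if not rows:
        raise FormatError(f"{path}: manifest has no data rows")
    return rows


def _read_records(path: Path) -> dict:
    """Parse one GenBank or FASTA file into {record id: SeqRecord}."""
    suffix = path.suffix.lower()
    fmt = "genbank" if suffix in {".gb", ".gbk", ".genbank"} else "fasta"
    try:
        records = list(SeqIO.parse(str(path), fmt))
        if not records and fmt == "fasta":
            records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Biopython raises assorted types on malformed input
        raise FormatError(f"{path}: failed to parse as {fmt}: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no sequence records found")
    return {rec.id: rec for rec in records}


def _record_features(rec) -> list[tuple]:
    feats = []
    for feat in getattr(rec, "features", []):
        if feat.type == "source":
            continue
        label = feat.qualifiers.get("label", feat.qualifiers.get("gene", [""]))[0]
        feats.append((feat.type, int(feat.location.start), int(feat.location.end), label))
    return feats


def load_design(manifest_path, name: str = None, base_dir=None) -> PlasmidDesign:
    """Load a plasmid design from a fragment manifest plus sequence files.

    The manifest is a TSV with columns (fragment_id, file, role,
    order_index, template_id); ``file`` is GenBank or FASTA, resolved
    relative to the manifest unless ``base_dir`` is given.  Each file may
    hold several records; a record whose id equals the fragment_id is
    preferred, otherwise a single-record file supplies its only record.
    """
    manifest_path = Path(manifest_path)
    base = Path(base_dir) if base_dir else manifest_path.parent
    rows = _read_manifest(manifest_path)
    seen = set()
    cache: dict[Path, dict] = {}
    fragments = []
    for row in rows:
        fid = row["fragment_id"]
        if fid in seen:
            raise ValidationError(f"duplicate fragment id in manifest: {fid}")
        seen.add(fid)
        fpath = base / row["file"]
        if fpath not in cache:
            cache[fpath] = _read_records(fpath)
        records = cache[fpath]
        rec = records.get(fid) if fid in records else (
            next(iter(records.values())) if len(records) == 1 else None
        )
        if rec is None:
            raise FormatError(
                f"{fpath}: no record named {fid!r} and file is not single-record"
            )
        fragments.append(
            Fragment(
                id=fid,
                sequence=validate_dna(str(rec.seq), context=f"fragment {fid}"),
                role=Role(row["role"]),
                template_id=row["template_id"],
                order_index=row["order_index"],
                features=_record_features(rec),
            )
        )
    return PlasmidDesign.from_fragments(name or manifest_path.stem, fragments)
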