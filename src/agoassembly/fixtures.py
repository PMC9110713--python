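"""Synthetic plasmid designs with controlled statistical structure.

Generates random multi-fragment circular designs whose fragment counts,
size range, GC content and internal repeat structure emulate realistic
assembly jobs (3-11 fragments of a few hundred bp to a few kb, GC from
AT-rich to ~75%, optionally several identical internal repeats such as
reused promoter sequences).  Everything is reproducible from one integer
seed; each component draws from its own named stream so adding a
component never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Fragment, PlasmidDesign, Role, gc_content
from .errors import ValidationError

# fixed stream ids: appending here must not renumber existing entries
_STREAMS = {"sizes": 0, "bases": 1, "repeat": 2, "placement": 3, "conc": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass
class FixtureSpec:
    """Parameters of one synthetic design.

    Defaults reflect a typical mid-size assembly: 5 fragments of
    0.8-2.5 kb at balanced GC, no planted repeats.
    """

    n_fragments: int = 5
    size_range: tuple = (800, 2500)
    gc_target: float = 0.5
    n_repeats: int = 0
    repeat_length: int = 500
    seed: int = 0
    gc_tolerance: float = 0.03  # realized per-fragment GC within ±3 pp of target

    def __post_init__(self):
        lo, hi = self.size_range
        if self.n_fragments < 1:
            raise ValidationError("n_fragments must be >= 1")
        if lo < 100:
            raise ValidationError("minimum fragment size must be >= 100 bp")
        if hi < lo:
            raise ValidationError("size_range must be (min, max) with min <= max")
        if not 0.0 <= self.gc_target <= 1.0:
            raise ValidationError("gc_target must be in [0, 1]")
        if self.n_repeats < 0:
            raise ValidationError("n_repeats must be >= 0")
        if self.n_repeats:
            if self.repeat_length >= lo:
                raise ValidationError("repeat_length must be shorter than the smallest fragment")
            if self.n_repeats > self.n_fragments:
                raise ValidationError("cannot plant more repeats than fragments")
            # repeat must fit strictly inside a fragment, 40 bp clear of each end
            if self.repeat_length + 2 * 40 > lo:
                raise ValidationError(
                    "repeat_length + 80 bp of end clearance exceeds the minimum fragment size"
                )


def _random_seq(rng: np.random.Generator, length: int, gc: float, tol: float) -> str:
    """Draw bases i.i.d. with P(G)=P(C)=gc/2; reject until realized GC is in band."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.array(list("ACGT"))
    lo, hi = max(0.0, gc - tol), min(1.0, gc + tol)
    for _ in range(500):
        seq = "".join(rng.choice(alphabet, size=length, p=p))
        if lo <= gc_content(seq) <= hi:
            return seq
    raise ValidationError(
        f"could not realize GC {gc:.2f}±{tol:.2f} at length {length} after 500 draws"
    )


def generate_design(spec: FixtureSpec, name: str = None) -> PlasmidDesign:
    """Build a circular design matching ``spec``; byte-identical under one seed.

    If ``spec.n_repeats > 0`` an identical ``repeat_length`` subsequence is
    planted internally in that many distinct fragments, never within 40 bp
    of a fragment end, so every guide search space stays repeat-free by
    construction.
    """
    size_rng = _rng(spec.seed, "sizes")
    base_rng = _rng(spec.seed, "bases")
    lo, hi = spec.size_range
    sizes = size_rng.integers(lo, hi + 1, size=spec.n_fragments)
    seqs = [_random_seq(base_rng, int(s), spec.gc_target, spec.gc_tolerance) for s in sizes]

    if spec.n_repeats:
        rep_rng = _rng(spec.seed, "repeat")
        place_rng = _rng(spec.seed, "placement")
        repeat = _random_seq(rep_rng, spec.repeat_length, spec.gc_target, spec.gc_tolerance)
        hosts = place_rng.choice(spec.n_fragments, size=spec.n_repeats, replace=False)
        for h in sorted(int(x) for x in hosts):
            L = len(seqs[h])
            pos = int(place_rng.integers(40, L - 40 - spec.repeat_length + 1))
            seqs[h] = seqs[h][:pos] + repeat + seqs[h][pos + spec.repeat_length :]

    fragments = [
        Fragment(
            id=f"f{i+1}",
            sequence=seq,
            role=Role.BACKBONE if i == 0 else Role.INSERT,
            template_id=f"t{i+1}",
            order_index=i,
        )
        for i, seq in enumerate(seqs)
    ]
    return PlasmidDesign.from_fragments(name or f"fixture_seed{spec.seed}", fragments)


def generate_concentration_table(
    design: PlasmidDesign,
    seed: int,
    conc_range: tuple = (20.0, 150.0),
) -> pd.DataFrame:
    """Simulated post-PCR fragment concentrations (ng/µL), uniform in range."""
    rng = _rng(seed, "conc")
    lo, hi = conc_range
    conc = rng.uniform(lo, hi, size=design.n_fragments)
    return pd.DataFrame(
        {
            "fragment_id": [f.id for f in design.fragments],
            "ng_per_uL": np.round(conc, 2),
        }
    )


def write_fixture(design: PlasmidDesign, outdir, concentrations: pd.DataFrame = None) -> dict:
    """Write a design as per-fragment FASTA files + manifest TSV (+ CSV).

    Also writes the circular target as a GenBank record annotated with one
    misc_feature per fragment, so file round-trips are testable.  Returns
    the paths written.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio.SeqFeature import SeqFeature, SimpleLocation
    from Bio import SeqIO

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    manifest_rows = ["fragment_id\tfile\trole\torder_index\ttemplate_id"]
    for frag in design.fragments:
        fa = out / f"{frag.id}.fasta"
        fa.write_text(f">{frag.id}\n{frag.sequence}\n")
        paths[frag.id] = fa
        manifest_rows.append(
            f"{frag.id}\t{fa.name}\t{frag.role.value}\t{frag.order_index}\t{frag.template_id or ''}"
        )
    manifest = out / "manifest.tsv"
    manifest.write_text("\n".join(manifest_rows) + "\n")
    paths["manifest"] = manifest

    rec = SeqRecord(Seq(design.target_sequence), id=design.name, name=design.name[:16],
                    description="synthetic circular design")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular"
    pos = 0
    for frag in design.fragments:
        rec.features.append(
            SeqFeature(
                SimpleLocation(pos, pos + len(frag), strand=1),
                type="misc_feature",
                qualifiers={"label": [frag.id]},
            )
        )
        pos += len(frag)
    gb = out / f"{design.name}.gb"
    SeqIO.write([rec], str(gb), "genbank")
    paths["genbank"] = gb

    if concentrations is not None:
        csv = out / "concentrations.csv"
        concentrations.to_csv(csv, index=False)
        paths["concentrations"] = csv
    return paths


def count_planted_repeats(design: PlasmidDesign, repeat: str) -> int:
    """Number of fragments containing ``repeat`` at least once (exact search)."""
    return sum(1 for f in design.fragments if repeat in f.sequence)


def planted_repeat(spec: FixtureSpec) -> str:
    """The exact repeat sequence a given spec plants (empty if none)."""
    if not spec.n_repeats:
        return ""
    rep_rng = _rng(spec.seed, "repeat")
    return _random_seq(rep_rng, spec.repeat_length, spec.gc_target, spec.gc_tolerance)
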