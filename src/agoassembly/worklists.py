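"""Liquid-handler picklist generation for the robotic assembly steps.

Every step compiles to a flat table of transfers (source plate/well →
destination plate/well, volume).  Acoustic transfers (volumes below
3 µL) are written in nL with an Echo-style cherry-pick header; larger
volumes route to a tip-based handler and are written in µL.  PCR plates
hold at most 92 reactions, filled column-major (A1→H1, A2→…) with wells
A1 and H12 reserved for the sizing ladder.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, field
import pandas as pd

from .errors import ValidationError

ACOUSTIC_MAX_UL = 3.0
ACOUSTIC_GRANULARITY_NL = 2.5
DSDNA_G_PER_MOL_PER_BP = 657.0
PCR_PLATE_CAPACITY = 92
RESERVED_WELLS_96 = ("A1", "H12")  # DNA ladder wells

WELL_96_RE = re.compile(r"^[A-H](1[0-2]|[1-9])$")
WELL_384_RE = re.compile(r"^[A-P](1[0-9]|2[0-4]|[1-9])$")


def validate_well(well: str, plate_format: int) -> str:
    pattern = WELL_96_RE if plate_format == 96 else WELL_384_RE
    if plate_format not in (96, 384):
        raise ValidationError(f"unsupported plate format {plate_format}")
    if not pattern.match(well):
        raise ValidationError(f"bad well id {well!r} for {plate_format}-well plate")
    return well


def wells_column_major(plate_format: int = 96, skip=RESERVED_WELLS_96):
    """Well ids in column-major fill order (A1, B1, ... H1, A2, ...)."""
    n_rows = 8 if plate_format == 96 else 16
    n_cols = 12 if plate_format == 96 else 24
    rows = string.ascii_uppercase[:n_rows]
    skip = set(skip or ())
    out = []
    for col in range(1, n_cols + 1):
        for row in rows:
            well = f"{row}{col}"
            if well not in skip:
                out.append(well)
    return out


@dataclass
class TransferRow:
    source_plate: str
    source_well: str
    dest_plate: str
    dest_well: str
    volume: float  # in the picklist's unit
    comment: str = ""


@dataclass
class Picklist:
    """One robotic step: named, typed list of transfers."""

    step: str
    instrument: str  # "acoustic" | "tip_based"
    rows: list = field(default_factory=list)

    ACOUSTIC_HEADER = [
        "Source Plate Name", "Source Well", "Destination Plate Name",
        "Destination Well", "Transfer Volume",
    ]
    TIP_HEADER = ["SourcePlate", "SourceWell", "DestPlate", "DestWell", "Volume_uL"]

    def __post_init__(self):
        if self.instrument not in ("acoustic", "tip_based"):
            raise ValidationError("instrument must be 'acoustic' or 'tip_based'")

    @property
    def unit(self) -> str:
        return "nL" if self.instrument == "acoustic" else "uL"

    def add(self, source_plate, source_well, dest_plate, dest_well, volume, comment=""):
        if volume <= 0:
            raise ValidationError(f"{self.step}: non-positive volume for {dest_well}")
        if self.instrument == "acoustic":
            if volume / 1000.0 >= ACOUSTIC_MAX_UL:
                raise ValidationError(
                    f"{self.step}: acoustic transfer of {volume} nL is >= 3 µL; "
                    "route it to the tip-based handler"
                )
            if volume < ACOUSTIC_GRANULARITY_NL:
                raise ValidationError(
                    f"{self.step}: {volume} nL below the {ACOUSTIC_GRANULARITY_NL} nL "
                    "instrument floor"
                )
        self.rows.append(
            TransferRow(source_plate, source_well, dest_plate, dest_well, volume, comment)
        )

    def to_frame(self) -> pd.DataFrame:
        header = self.ACOUSTIC_HEADER if self.instrument == "acoustic" else self.TIP_HEADER
        return pd.DataFrame(
            [
                [r.source_plate, r.source_well, r.dest_plate, r.dest_well, r.volume]
                for r in self.rows
            ],
            columns=header,
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, step: str = "loaded") -> "Picklist":
        df = pd.read_csv(path)
        if list(df.columns) == cls.ACOUSTIC_HEADER:
            instrument = "acoustic"
        elif list(df.columns) == cls.TIP_HEADER:
            instrument = "tip_based"
        else:
            raise ValidationError(f"{path}: unrecognized picklist header {list(df.columns)}")
        pl = cls(step=step, instrument=instrument)
        for _, r in df.iterrows():
            pl.add(*r.tolist())
        return pl


@dataclass
class PlateLayout:
    plate_id: str
    format: int = 96
    contents: dict = field(default_factory=dict)  # well -> description
    reserved: tuple = RESERVED_WELLS_96

    def assign(self, well: str, content: str):
        validate_well(well, self.format)
        if well in self.reserved:
            raise ValidationError(f"{self.plate_id}: well {well} is reserved")
        if well in self.contents:
            raise ValidationError(f"{self.plate_id}: well {well} already assigned")
        self.contents[well] = content


# ---------------------------------------------------------------------------


def dedupe_oligos(oligo_rows: list):
    """Deduplicate a batch's oligo orders by exact sequence.

    ``oligo_rows`` holds dicts with keys (name, sequence, consumer).
    Returns (order list, usage map, counts) where the order keeps the
    first-seen name per unique sequence, the usage map lists every
    consumer of each sequence, and counts reports total vs unique.
    """
    if not oligo_rows:
        raise ValidationError("empty oligo batch")
    order, usage = [], {}
    for row in oligo_rows:
        seq = row["sequence"].upper()
        if seq not in usage:
            usage[seq] = []
            order.append({"name": row["name"], "sequence": seq})
        usage[seq].append(row.get("consumer", row["name"]))
    counts = {"total": len(oligo_rows), "unique": len(order)}
    return order, usage, counts


def hydration_picklist(sheet: pd.DataFrame, target_conc_uM: float = 100.0,
                       water_source=("WaterReservoir", "A1"),
                       dest_plate: str = "OligoPlate1") -> Picklist:
    """Water volumes rehydrating lyophilized oligos to the target molarity.

    The manufacturer sheet needs columns (well, nmol); volume_µL =
    nmol / target_µM × 1000.  Rows come out in plate-scan order of the
    sheet; rows missing nmol are collected into one error.
    """
    if target_conc_uM <= 0:
        raise ValidationError("target concentration must be > 0")
    cols = {c.lower(): c for c in sheet.columns}
    if "well" not in cols or "nmol" not in cols:
        raise ValidationError("manufacturer sheet needs columns (well, nmol)")
    missing = sheet[sheet[cols["nmol"]].isna()][cols["well"]].tolist()
    if missing:
        raise ValidationError(f"missing nmol for wells: {missing}")
    pl = Picklist(step="hydration", instrument="tip_based")
    for _, row in sheet.iterrows():
        vol_uL = float(row[cols["nmol"]]) / target_conc_uM * 1000.0
        pl.add(water_source[0], water_source[1], dest_plate, row[cols["well"]],
               round(vol_uL, 3))
    return pl


@dataclass
class PcrReaction:
    """One PCR: which primers and template go into one destination well."""

    name: str
    fwd_well: str
    rev_well: str
    template_well: str
    primer_plate: str = "Primers384"
    template_plate: str = "Templates384"


def pcr_setup_picklists(
    reactions: list,
    primer_nL: float = 500.0,
    template_nL: float = 500.0,
    plate_prefix: str = "PCR",
):
    """Pack PCRs into 96-well plates (92 per plate, A1/H12 reserved) and
    emit one acoustic picklist per plate transferring both primers and the
    template into each reaction well."""
    if not reactions:
        raise ValidationError("no reactions to set up")
    for rx in reactions:
        for well, what in ((rx.fwd_well, "fwd"), (rx.rev_well, "rev"),
                           (rx.template_well, "template")):
            if not well:
                raise ValidationError(f"reaction {rx.name}: unassigned {what} source well")
            validate_well(well, 384)
    order = wells_column_major(96, skip=RESERVED_WELLS_96)
    picklists, layouts = [], []
    for p in range(0, len(reactions), PCR_PLATE_CAPACITY):
        chunk = reactions[p : p + PCR_PLATE_CAPACITY]
        plate_id = f"{plate_prefix}{p // PCR_PLATE_CAPACITY + 1}"
        layout = PlateLayout(plate_id=plate_id)
        pl = Picklist(step=f"pcr_setup_{plate_id}", instrument="acoustic")
        for rx, well in zip(chunk, order):
            layout.assign(well, rx.name)
            pl.add(rx.primer_plate, rx.fwd_well, plate_id, well, primer_nL, rx.name)
            pl.add(rx.primer_plate, rx.rev_well, plate_id, well, primer_nL, rx.name)
            pl.add(rx.template_plate, rx.template_well, plate_id, well, template_nL, rx.name)
        picklists.append(pl)
        layouts.append(layout)
    return picklists, layouts


def equimolar_mix_picklist(
    concentrations: pd.DataFrame,
    fragment_lengths: dict,
    total_mass_ng: float = 1000.0,
    source_plate: str = "Fragments96",
    source_wells: dict = None,
    dest=("AssemblyPlate", "A1"),
):
    """Volumes mixing purified fragments equimolar to a total mass.

    Equimolarity makes target mass proportional to length:
    m_i = total × L_i / Σ L_j, volume_i = m_i / conc_i.  Sub-3-µL volumes
    route to the acoustic handler (in nL); the rest to tips (µL).
    Volumes below the 2.5 nL acoustic floor are returned as error rows
    instead of transfers.  Returns (acoustic, tip_based, errors).
    """
    if total_mass_ng <= 0:
        raise ValidationError("total mass must be > 0")
    cols = {c.lower(): c for c in concentrations.columns}
    fid_col = cols.get("fragment_id") or list(concentrations.columns)[0]
    conc_col = cols.get("ng_per_ul", cols.get("ng_per_ul".lower()))
    if conc_col is None:
        conc_col = next(c for c in concentrations.columns if "ng" in c.lower())
    total_len = sum(fragment_lengths.values())
    acoustic = Picklist(step="equimolar_mix", instrument="acoustic")
    tips = Picklist(step="equimolar_mix_large", instrument="tip_based")
    errors = []
    default_wells = wells_column_major(96, skip=())
    for i, (_, row) in enumerate(concentrations.iterrows()):
        fid = row[fid_col]
        conc = float(row[conc_col])
        if conc <= 0:
            raise ValidationError(f"fragment {fid}: non-positive concentration")
        if fid not in fragment_lengths:
            raise ValidationError(f"fragment {fid}: unknown length")
        mass = total_mass_ng * fragment_lengths[fid] / total_len
        vol_uL = mass / conc
        well = (source_wells or {}).get(fid, default_wells[i])
        # volumes written at full precision: equimolarity is exact arithmetic,
        # the instrument quantizes at dispense time
        if vol_uL * 1000.0 < ACOUSTIC_GRANULARITY_NL:
            errors.append({"fragment_id": fid, "volume_nL": vol_uL * 1000.0,
                           "reason": "below acoustic granularity"})
        elif vol_uL < ACOUSTIC_MAX_UL:
            acoustic.add(source_plate, well, dest[0], dest[1], vol_uL * 1000.0, fid)
        else:
            tips.add(source_plate, well, dest[0], dest[1], vol_uL, fid)
    return acoustic, tips, errors


def failed_pcr_picklist(
    qc: pd.DataFrame,
    transfer_uL: float = 20.0,
    dest_prefix: str = "Retry",
):
    """Consolidate failed PCRs into fresh plates (92 per plate, A1/H12 kept
    free); returns (picklist, old→new well mapping)."""
    cols = {c.lower(): c for c in qc.columns}
    for need in ("plate", "well", "passed"):
        if need not in cols:
            raise ValidationError(f"QC table needs column {need!r}")
    failed = qc[~qc[cols["passed"]].astype(bool)]
    pl = Picklist(step="failed_pcr_consolidation", instrument="tip_based")
    mapping = {}
    order = wells_column_major(96, skip=RESERVED_WELLS_96)
    for i, (_, row) in enumerate(failed.iterrows()):
        plate_no = i // PCR_PLATE_CAPACITY + 1
        new_well = order[i % PCR_PLATE_CAPACITY]
        dest_plate = f"{dest_prefix}{plate_no}"
        pl.add(row[cols["plate"]], row[cols["well"]], dest_plate, new_well, transfer_uL)
        mapping[(row[cols["plate"]], row[cols["well"]])] = (dest_plate, new_well)
    return pl, mapping
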