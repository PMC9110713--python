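"""YAML-backed configuration bundling every tunable threshold.

One :class:`AssemblyConfig` object carries the digestion criteria, cut
geometry, ligation fidelity model, primer rules and digest separation
criteria; each CLI subcommand accepts ``--config config.yaml`` and any
omitted key keeps its documented default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .digest import SeparationCriteria
from .errors import ValidationError
from .fidelity import FidelityModel
from .guides import CutGeometry, DigestionCriteria
from .primers import PrimerConfig, TmParameters


@dataclass
class AssemblyConfig:
    digestion: DigestionCriteria = field(default_factory=DigestionCriteria)
    geometry: CutGeometry = field(default_factory=CutGeometry)
    primers: PrimerConfig = field(default_factory=PrimerConfig)
    separation: SeparationCriteria = field(default_factory=SeparationCriteria)
    fidelity_threshold: float = 8.0
    fidelity_table: str = ""  # path to a replacement mismatch TSV; empty = packaged

    def fidelity_model(self) -> FidelityModel:
        if self.fidelity_table:
            return FidelityModel.from_tsv(self.fidelity_table, self.fidelity_threshold)
        return FidelityModel.packaged_default(self.fidelity_threshold)


def _build(cls, data: dict, label: str):
    known = {f.name for f in fields(cls)}
    bad = set(data) - known
    if bad:
        raise ValidationError(f"config section {label}: unknown key(s) {sorted(bad)}")
    if cls is PrimerConfig and "tm_params" in data:
        data = dict(data)
        data["tm_params"] = TmParameters(**data["tm_params"])
    return cls(**data)


def load_config(path=None) -> AssemblyConfig:
    """Read an AssemblyConfig from YAML; missing file/keys fall back to defaults."""
    if path is None:
        return AssemblyConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = AssemblyConfig(
        digestion=_build(DigestionCriteria, raw.get("digestion", {}), "digestion"),
        geometry=_build(CutGeometry, raw.get("geometry", {}), "geometry"),
        primers=_build(PrimerConfig, raw.get("primers", {}), "primers"),
        separation=_build(SeparationCriteria, raw.get("separation", {}), "separation"),
        fidelity_threshold=float(raw.get("fidelity_threshold", 8.0)),
        fidelity_table=str(raw.get("fidelity_table", "") or ""),
    )
    return cfg
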