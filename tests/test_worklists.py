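"""Picklist compilation: packing, routing, volumes, parse-back."""

import pandas as pd
import pytest

from agoassembly.errors import ValidationError
from agoassembly.fixtures import FixtureSpec, generate_concentration_table, generate_design
from agoassembly.worklists import (
    DSDNA_G_PER_MOL_PER_BP,
    PcrReaction,
    Picklist,
    dedupe_oligos,
    equimolar_mix_picklist,
    failed_pcr_picklist,
    hydration_picklist,
    pcr_setup_picklists,
    validate_well,
    wells_column_major,
)


class TestWells:
    def test_column_major_order_skips_reserved(self):
        order = wells_column_major(96)
        assert order[0] == "B1"  # A1 reserved
        assert order[1] == "C1"
        assert "A1" not in order and "H12" not in order
        assert len(order) == 94

    @pytest.mark.parametrize("well,fmt,ok", [
        ("A1", 96, True), ("H12", 96, True), ("I1", 96, False), ("A13", 96, False),
        ("P24", 384, True), ("Q1", 384, False), ("A25", 384, False),
    ])
    def test_well_id_validation(self, well, fmt, ok):
        if ok:
            assert validate_well(well, fmt) == well
        else:
            with pytest.raises(ValidationError):
                validate_well(well, fmt)


class TestDedupeOligos:
    def test_shared_primer_ordered_once_with_two_consumers(self):
        rows = [
            {"name": "p1_F", "sequence": "ACGTACGTACGTACG", "consumer": "plasmidA"},
            {"name": "p1_F", "sequence": "ACGTACGTACGTACG", "consumer": "plasmidB"},
            {"name": "p2_F", "sequence": "TTTTACGTACGTACG", "consumer": "plasmidA"},
        ]
        order, usage, counts = dedupe_oligos(rows)
        assert counts == {"total": 3, "unique": 2}
        assert usage["ACGTACGTACGTACG"] == ["plasmidA", "plasmidB"]

    def test_no_duplicates_identity(self):
        rows = [{"name": f"o{i}", "sequence": "ACGT" * 4 + "ACGT"[:i+1], "consumer": "x"}
                for i in range(3)]
        order, _, counts = dedupe_oligos(rows)
        assert counts["unique"] == counts["total"] == 3

    def test_unique_count_equals_set_oracle(self, design8, primers8):
        from agoassembly.primers import primer_order_table

        rows = []
        for copy in ("batchA", "batchB"):  # same design ordered twice
            for r in primer_order_table(primers8):
                rows.append({"name": r["name"], "sequence": r["sequence"],
                             "consumer": copy})
        _, _, counts = dedupe_oligos(rows)
        assert counts["unique"] == len({r["sequence"] for r in rows})
        assert counts["total"] == 2 * counts["unique"]


class TestHydration:
    def test_volume_arithmetic(self):
        sheet = pd.DataFrame({"well": ["A1", "B1"], "nmol": [10.0, 2.5]})
        pl = hydration_picklist(sheet, target_conc_uM=100.0)
        assert [r.volume for r in pl.rows] == [100.0, 25.0]

    def test_full_sheet_matches_hand_arithmetic(self):
        wells = wells_column_major(96, skip=())
        nmols = [(i % 37 + 1) * 0.5 for i in range(96)]
        sheet = pd.DataFrame({"well": wells[:96], "nmol": nmols})
        pl = hydration_picklist(sheet, target_conc_uM=100.0)
        for row, nmol in zip(pl.rows, nmols):
            assert row.volume == pytest.approx(nmol / 100.0 * 1000.0)

    def test_missing_nmol_lists_wells(self):
        sheet = pd.DataFrame({"well": ["A1", "B1"], "nmol": [10.0, None]})
        with pytest.raises(ValidationError, match="B1"):
            hydration_picklist(sheet)


class TestPcrSetup:
    def _reactions(self, n):
        src = wells_column_major(384, skip=())
        return [
            PcrReaction(name=f"rx{i}", fwd_well=src[i % 384], rev_well=src[(i + 1) % 384],
                        template_well=src[(i + 2) % 384])
            for i in range(n)
        ]

    def test_150_reactions_pack_as_92_plus_58(self):
        picklists, layouts = pcr_setup_picklists(self._reactions(150))
        assert len(layouts) == 2
        assert len(layouts[0].contents) == 92
        assert len(layouts[1].contents) == 58
        for layout in layouts:
            assert "A1" not in layout.contents
            assert "H12" not in layout.contents

    def test_single_reaction_still_reserves_ladder_wells(self):
        _, layouts = pcr_setup_picklists(self._reactions(1))
        assert len(layouts) == 1
        assert set(layouts[0].contents) == {"B1"}

    def test_three_transfers_per_reaction_parse_back(self, tmp_path):
        picklists, _ = pcr_setup_picklists(self._reactions(10))
        pl = picklists[0]
        assert len(pl.rows) == 30
        path = tmp_path / "pcr.csv"
        pl.to_csv(path)
        back = Picklist.from_csv(path)
        per_dest = {}
        for r in back.rows:
            per_dest.setdefault(r.dest_well, 0.0)
            per_dest[r.dest_well] += r.volume
        assert all(v == pytest.approx(1500.0) for v in per_dest.values())

    def test_unassigned_source_well_is_compile_error(self):
        rx = PcrReaction(name="bad", fwd_well="", rev_well="A1", template_well="A2")
        with pytest.raises(ValidationError, match="bad"):
            pcr_setup_picklists([rx])


class TestEquimolarMix:
    def test_mass_proportional_to_length(self):
        conc = pd.DataFrame({"fragment_id": ["a", "b"], "ng_per_uL": [100.0, 100.0]})
        acoustic, tips, errors = equimolar_mix_picklist(
            conc, {"a": 1000, "b": 2000}, total_mass_ng=1000.0
        )
        vols = {r.comment: r for r in acoustic.rows + tips.rows}
        got_a = vols["a"].volume / (1000.0 if vols["a"] in acoustic.rows else 1.0)
        # volumes in their native units; recompute masses
        mass = {}
        for pl, unit in ((acoustic, 1e-3), (tips, 1.0)):
            for r in pl.rows:
                mass[r.comment] = r.volume * unit * 100.0  # uL * ng/uL
        assert mass["a"] == pytest.approx(1000.0 / 3, rel=1e-6)
        assert mass["b"] == pytest.approx(2000.0 / 3, rel=1e-6)

    def test_equal_lengths_equal_concentrations_equal_volumes(self):
        conc = pd.DataFrame({"fragment_id": list("abc"), "ng_per_uL": [80.0] * 3})
        acoustic, tips, errors = equimolar_mix_picklist(conc, {k: 1500 for k in "abc"})
        rows = acoustic.rows + tips.rows
        assert len({r.volume for r in rows}) == 1
        assert not errors

    def test_molar_amounts_equal_to_1e9_relative(self, design5):
        conc = generate_concentration_table(design5, seed=8)
        lengths = {f.id: len(f) for f in design5.fragments}
        acoustic, tips, errors = equimolar_mix_picklist(conc, lengths)
        assert not errors
        conc_map = dict(zip(conc.fragment_id, conc.ng_per_uL))
        moles = []
        for pl, to_uL in ((acoustic, 1e-3), (tips, 1.0)):
            for r in pl.rows:
                vol_uL = r.volume * to_uL
                mass_ng = vol_uL * conc_map[r.comment]
                moles.append(mass_ng / (DSDNA_G_PER_MOL_PER_BP * lengths[r.comment]))
        assert len(moles) == design5.n_fragments
        lo, hi = min(moles), max(moles)
        assert (hi - lo) / hi <= 1e-9

    def test_acoustic_routing_under_3uL(self):
        conc = pd.DataFrame({"fragment_id": ["hi", "lo"], "ng_per_uL": [150.0, 20.0]})
        acoustic, tips, _ = equimolar_mix_picklist(conc, {"hi": 1000, "lo": 1000},
                                                   total_mass_ng=500.0)
        assert {r.comment for r in acoustic.rows} == {"hi"}  # 250/150 = 1.67 uL
        assert {r.comment for r in tips.rows} == {"lo"}  # 250/20 = 12.5 uL


class TestFailedPcr:
    def test_no_failures_empty_picklist(self):
        qc = pd.DataFrame({"plate": ["PCR1"] * 3, "well": ["B1", "C1", "D1"],
                           "passed": [True, True, True]})
        pl, mapping = failed_pcr_picklist(qc)
        assert pl.rows == [] and mapping == {}

    def test_scattered_failures_consolidated_in_order(self):
        qc = pd.DataFrame({
            "plate": ["PCR1", "PCR1", "PCR2", "PCR2", "PCR2"],
            "well": ["C3", "F7", "B1", "D9", "H11"],
            "passed": [False, False, False, False, False],
        })
        pl, mapping = failed_pcr_picklist(qc)
        assert len(pl.rows) == 5
        dests = [r.dest_well for r in pl.rows]
        assert dests == wells_column_major(96)[:5]
        assert set(mapping) == {("PCR1", "C3"), ("PCR1", "F7"), ("PCR2", "B1"),
                                ("PCR2", "D9"), ("PCR2", "H11")}

    def test_parse_back_equals_failure_set(self, tmp_path):
        qc = pd.DataFrame({"plate": ["P1"] * 4, "well": ["B2", "C2", "D2", "E2"],
                           "passed": [False, True, False, True]})
        pl, _ = failed_pcr_picklist(qc)
        path = tmp_path / "fail.csv"
        pl.to_csv(path)
        back = Picklist.from_csv(path)
        assert {r.source_well for r in back.rows} == {"B2", "D2"}


class TestPicklistRules:
    def test_acoustic_volume_cap_enforced(self):
        pl = Picklist(step="s", instrument="acoustic")
        with pytest.raises(ValidationError, match="3 µL"):
            pl.add("P", "A1", "Q", "B1", 3000.0)

    def test_acoustic_granularity_floor(self):
        pl = Picklist(step="s", instrument="acoustic")
        with pytest.raises(ValidationError, match="floor"):
            pl.add("P", "A1", "Q", "B1", 1.0)

    def test_nonpositive_volume_rejected(self):
        pl = Picklist(step="s", instrument="tip_based")
        with pytest.raises(ValidationError):
            pl.add("P", "A1", "Q", "B1", 0.0)
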