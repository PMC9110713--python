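"""Recognition-site enumeration, digestion filters, guide derivation."""

import random

import pytest

from agoassembly.core import Fragment, PlasmidDesign, gc_content, revcomp
from agoassembly.errors import DesignInfeasibleError, ValidationError
from agoassembly.fixtures import FixtureSpec, generate_design
from agoassembly.guides import (
    CutGeometry,
    DEFAULT_GEOMETRY,
    DigestionCriteria,
    EnzymeMode,
    GCPreference,
    OfftargetLibrary,
    apply_digestion_filters,
    build_search_space,
    derive_guides,
    enumerate_candidates,
    select_sites,
    suggest_enzyme_mode,
    window_target_start,
)


class TestSearchSpace:
    def test_is_40_plus_40_around_each_boundary(self, design5):
        target = design5.target_sequence
        for j in design5.junctions:
            space = build_search_space(design5, j.index)
            assert len(space) == 80
            up = design5.fragment(j.upstream_fragment_id).sequence
            down = design5.fragment(j.downstream_fragment_id).sequence
            assert space == up[-40:] + down[:40]

    def test_wraparound_junction_spans_origin(self, design5):
        last = design5.junctions[-1]
        up = design5.fragment(last.upstream_fragment_id).sequence
        down = design5.fragment(last.downstream_fragment_id).sequence
        assert last.search_space == up[-40:] + down[:40]
        assert last.boundary == 0  # boundary is the origin itself

    def test_synthetic_concatenation(self):
        frags = [Fragment(id="a", sequence="A" * 100, order_index=0),
                 Fragment(id="b", sequence="C" * 100, order_index=1)]
        d = PlasmidDesign.from_fragments("x", frags)
        assert build_search_space(d, 0) == "A" * 40 + "C" * 40


class TestEnumerateCandidates:
    def test_80nt_space_yields_57_windows(self):
        space = "".join(random.Random(0).choice("ACGT") for _ in range(80))
        wins = enumerate_candidates(space)
        assert len(wins) == 57
        assert all(len(w) == 24 for _, w in wins)

    @pytest.mark.parametrize("L", [24, 30, 57, 80, 100])
    def test_count_is_length_minus_23(self, L):
        space = "".join(random.Random(L).choice("ACGT") for _ in range(L))
        assert len(enumerate_candidates(space)) == L - 23

    def test_boundary_windows_cover_first_and_last_base(self):
        space = "".join(random.Random(1).choice("ACGT") for _ in range(80))
        offsets = {off for off, _ in enumerate_candidates(space)}
        assert {0, 56} <= offsets

    def test_center_out_scan_order(self):
        space = "".join(random.Random(2).choice("ACGT") for _ in range(80))
        order = [off for off, _ in enumerate_candidates(space)]
        assert order[:5] == [28, 27, 29, 26, 30]
        assert sorted(order) == list(range(57))

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            enumerate_candidates("ACGT" * 5)


class TestDeriveGuides:
    def test_lengths_and_sticky_is_central_12mer(self):
        rng = random.Random(3)
        for _ in range(50):
            w = "".join(rng.choice("ACGT") for _ in range(24))
            gt, gb, sticky = derive_guides(w)
            assert len(gt) == len(gb) == 16
            assert sticky == w[6:18]
            # guides pair the window strands and jointly cover all 24 bp
            assert gt == revcomp(w[:16])
            assert gb == w[8:24]

    def test_bad_geometry_rejected(self):
        with pytest.raises(ValidationError):
            CutGeometry(guide_length=16, cut_from_guide5=16)
        with pytest.raises(ValidationError):
            CutGeometry(guide_length=16, cut_from_guide5=2)  # cuts cross over

    def test_alternative_geometry_changes_overhang(self):
        geo = CutGeometry(guide_length=16, cut_from_guide5=9)  # cuts at 7|17
        _, _, sticky = derive_guides("ACGTACGTACGTACGTACGTACGT", geo)
        assert len(sticky) == 10


class TestDigestionFilters:
    def test_homopolymer_run_of_5_fails_run_of_4_passes(self):
        win_bad = "GCGC" + "AAAAA" + "GCGTGCGTGCGTGCG"  # A-run of 5
        assert len(win_bad) == 24
        assert not apply_digestion_filters(win_bad).outcome("homopolymer").passed
        win_ok = "GCGC" + "AAAA" + "GCGTGCGTGCGTGCGT"  # boundary: run of exactly 4
        assert apply_digestion_filters(win_ok).outcome("homopolymer").passed
        win_t = "GCGC" + "TTTTT" + "GCGTGCGTGCGTGCG"
        assert not apply_digestion_filters(win_t).outcome("homopolymer").passed

    def test_gc_above_75_percent_fails(self):
        win_75 = "GCGCATGCGCGCATGCGCGCATGC"  # GC 18/24 = 75%, inclusive bound
        assert apply_digestion_filters(win_75).outcome("gc").passed
        win_hi = "GCGCATGCGCGCGCGCGCGCATGC"  # GC 20/24 ~ 83%
        assert not apply_digestion_filters(win_hi).outcome("gc").passed

    def test_gquad_motif_fails_either_strand(self):
        g4 = "GGGAGGGAGGGAGGGACGTACGTA"[:24]
        assert not apply_digestion_filters(g4).outcome("gquad").passed
        c4 = revcomp(g4)
        assert not apply_digestion_filters(c4).outcome("gquad").passed
        clean = "GACTGACTGACTGACTGACTGACT"
        assert apply_digestion_filters(clean).outcome("gquad").passed

    def test_offtarget_duplicate_sticky_end_detected(self):
        rng = random.Random(7)
        window = "".join(rng.choice("ACGT") for _ in range(24))
        sticky = window[6:18]
        filler = "".join(rng.choice("ACGT") for _ in range(200))
        target = window + filler + sticky + filler
        lib = OfftargetLibrary(k=12)
        lib.add_sequence("__target__", target, circular=True)
        rep = apply_digestion_filters(window, offtargets=lib, exclude_span=(0, 24))
        assert not rep.outcome("offtarget").passed
        # without the planted duplicate the same window passes
        lib2 = OfftargetLibrary(k=12)
        lib2.add_sequence("__target__", window + filler, circular=True)
        rep2 = apply_digestion_filters(window, offtargets=lib2, exclude_span=(0, 24))
        assert rep2.outcome("offtarget").passed

    def test_template_copy_of_locus_is_not_an_offtarget(self, design5):
        lib = OfftargetLibrary.from_design(design5, include_templates=True)
        j = design5.junctions[0]
        site = j.chosen_site
        start = window_target_start(design5, 0)
        rep = apply_digestion_filters(
            site.sequence24, offtargets=lib, exclude_span=(start, start + 24)
        )
        assert rep.outcome("offtarget").passed


class TestEnzymeMode:
    def test_high_gc_fragments_force_mutant_only(self):
        mode, _ = suggest_enzyme_mode([0.73, 0.71], 0.5)
        assert mode is EnzymeMode.MUTANT_ONLY

    def test_low_window_gc_prefers_wild_type(self):
        mode, pref = suggest_enzyme_mode([0.5, 0.5], 0.10)
        assert mode is EnzymeMode.WT_AND_MUTANT
        assert pref is GCPreference.WT_PREFERRED

    def test_mid_gc_neutral(self):
        mode, pref = suggest_enzyme_mode([0.36], 0.30)
        assert mode is EnzymeMode.WT_AND_MUTANT
        assert pref is GCPreference.NEUTRAL

    def test_window_gc_50_prefers_mutant(self):
        _, pref = suggest_enzyme_mode([0.36], 0.50)
        assert pref is GCPreference.MUTANT_PREFERRED


class TestSelectSites:
    def test_all_junctions_resolved_and_reports_pass(self, design5):
        for j in design5.junctions:
            site = j.chosen_site
            assert site is not None
            assert site.filter_report.passed
            assert len(site.guide_top) == 16
            assert len(site.sticky_end) == 12

    def test_refiltering_finalized_sites_is_idempotent(self, design5):
        lib = OfftargetLibrary.from_design(design5)
        for j in design5.junctions:
            start = window_target_start(design5, j.index)
            rep = apply_digestion_filters(
                j.chosen_site.sequence24, offtargets=lib,
                exclude_span=(start, start + 24),
            )
            assert rep.passed

    def test_deterministic(self):
        spec = FixtureSpec(n_fragments=4, seed=21)
        a = select_sites(generate_design(spec))
        b = select_sites(generate_design(spec))
        assert [j.chosen_site.sequence24 for j in a.junctions] == \
            [j.chosen_site.sequence24 for j in b.junctions]

    def test_poly_a_search_space_infeasible_with_full_report(self):
        rng = random.Random(5)
        rand = lambda n: "".join(rng.choice("ACGT") for _ in range(n))
        # junction 0's entire 80-nt search space is poly-A by construction
        frags = [Fragment(id="a", sequence=rand(160) + "A" * 40, order_index=0),
                 Fragment(id="b", sequence="A" * 40 + rand(160), order_index=1)]
        d = PlasmidDesign.from_fragments("polyA", frags)
        with pytest.raises(DesignInfeasibleError) as exc:
            select_sites(d)
        reports = exc.value.reports
        assert len(reports) == 57
        assert all(not r.outcome("homopolymer").passed for r in reports)

    def test_sticky_ends_are_mutually_orthogonal(self, design8):
        from agoassembly.fidelity import orthogonality_check

        ends = [j.chosen_site.sticky_end for j in design8.junctions]
        assert orthogonality_check(ends).passed
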