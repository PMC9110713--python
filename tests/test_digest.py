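"""In-silico restriction digestion, plan selection, band matching."""

import random

import pytest

from agoassembly.core import revcomp
from agoassembly.digest import (
    Enzyme,
    EnzymeTable,
    Rejection,
    SeparationCriteria,
    common_enzymes,
    cut_positions,
    digest,
    evaluate_bands,
    match_bands,
    select_combinations,
)
from agoassembly.errors import ValidationError


def rand_circle(seed, n=3000):
    rng = random.Random(seed)
    return "".join(rng.choice("ACGT") for _ in range(n))


def plant(seq, site, positions):
    out = seq
    for p in positions:
        out = out[:p] + site + out[p + len(site):]
    return out


def brute_force_digest(seq, enzymes, table):
    """Independent quadratic scanner: rotate-and-match at every offset."""
    n = len(seq)
    cuts = set()
    for name in enzymes:
        e = table[name]
        m = len(e.site)
        for i in range(n):
            window = (seq + seq)[i : i + m]
            if _iupac_match(window, e.site):
                cuts.add((i + e.cut_top) % n)  # one event per duplex site
            elif _iupac_match(window, _rc_iupac(e.site)):
                cuts.add((i + m - e.cut_bottom) % n)
    if not cuts:
        return []
    ordered = sorted(cuts)
    bands = sorted(
        (ordered[(k + 1) % len(ordered)] - ordered[k]) % n or n
        for k in range(len(ordered))
    )
    return bands


_IUPAC_SETS = {"A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT",
               "S": "CG", "W": "AT", "K": "GT", "M": "AC", "B": "CGT",
               "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT"}


def _iupac_match(window, site):
    return len(window) == len(site) and all(
        c in _IUPAC_SETS[s] for c, s in zip(window, site)
    )


def _rc_iupac(site):
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
            "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D",
            "N": "N"}
    return "".join(comp[c] for c in reversed(site))


@pytest.fixture(scope="module")
def table():
    return EnzymeTable.packaged_default()


class TestDigest:
    def test_single_site_linearizes(self, table):
        seq = plant("A" * 2497 + "CGT" + "A" * 2500, "GAATTC", [1000])
        seq = rand_circle(0, 5000)
        seq = seq.replace("GAATTC", "GAATTA")  # clear stray sites
        seq = plant(seq, "GAATTC", [1000])
        assert digest(seq, "EcoRI", table) == [len(seq)]

    def test_two_cuts_circular_arithmetic(self, table):
        seq = rand_circle(1, 5000).replace("GAATTC", "GAATTA")
        seq = plant(seq, "GAATTC", [999, 2999])  # cuts at 1000 and 3000
        assert digest(seq, "EcoRI", table) == [2000, 3000]

    def test_no_cut_returns_empty(self, table):
        seq = rand_circle(2, 1000).replace("GAATTC", "GAATTA")
        assert digest(seq, "EcoRI", table) == []

    def test_matches_bruteforce_oracle_on_random_circles(self, table):
        rng = random.Random(3)
        names = table.names
        for trial in range(100):
            seq = rand_circle(100 + trial, rng.randint(500, 2000))
            enzymes = rng.sample(names, rng.randint(1, 2))
            assert digest(seq, enzymes, table) == brute_force_digest(seq, enzymes, table)

    def test_conservation_bands_sum_to_length(self, table):
        for trial in range(20):
            seq = rand_circle(trial, 4000)
            bands = digest(seq, ["EcoRI", "HindIII"], table)
            if bands:
                assert sum(bands) == len(seq)

    def test_cross_checked_against_biopython_restriction(self, table):
        from Bio.Restriction import EcoRI as BioEcoRI
        from Bio.Seq import Seq

        core = plant(rand_circle(7, 6000).replace("GAATTC", "GAATTA"),
                     "GAATTC", [500, 2345])
        seq = "TTC" + core[3:-3] + "GAA"  # third site spans the origin
        ours = list(cut_positions(seq, table["EcoRI"]))
        # Bio.Restriction reports 1-based positions of the base after the cut
        theirs = sorted((p - 1) % len(seq) for p in BioEcoRI.search(Seq(seq), linear=False))
        assert ours == theirs
        assert len(ours) == 3

    def test_unknown_enzyme_is_lookup_error(self, table):
        with pytest.raises(KeyError, match="NoSuchEnzyme"):
            digest("ACGT" * 100, "NoSuchEnzyme", table)

    def test_site_spanning_origin_found(self, table):
        seq = "ATTC" + rand_circle(9, 1000).replace("GAATTC", "GAATTA") + "GA"
        # site GAATTC spans the origin: last 2 + first 4 characters
        assert any(True for _ in [cut_positions(seq, table["EcoRI"])])
        assert len(cut_positions(seq, table["EcoRI"])) >= 1


class TestEvaluateBands:
    @pytest.mark.parametrize("bands,expected", [
        ([90, 2000], Rejection.TOO_SMALL),
        ([2000, 9800], Rejection.TOO_LARGE),
        ([1000, 1050], Rejection.TOO_CLOSE),
        ([], Rejection.NO_CUT),
    ])
    def test_rejections(self, bands, expected):
        accepted, reason, _ = evaluate_bands(bands)
        assert not accepted
        assert reason is expected

    def test_well_separated_bands_accepted(self):
        accepted, reason, ratio = evaluate_bands([1000, 1200, 3000])
        assert accepted and reason is None
        assert ratio == pytest.approx(200 / 1200)

    def test_gap_rule_uses_larger_band_by_default(self):
        # gap 105 vs larger band 1105: 105 < 110.5 -> rejected
        accepted, reason, _ = evaluate_bands([1000, 1105])
        assert not accepted and reason is Rejection.TOO_CLOSE
        # against the smaller band it would pass (105 >= 100)
        crit = SeparationCriteria(compare_to_larger=False)
        accepted, _, _ = evaluate_bands([1000, 1105], crit)
        assert accepted


class TestSelectCombinations:
    def test_accepted_plans_satisfy_all_criteria_independently(self, design5, table):
        plans = select_combinations(design5.target_sequence, table)
        assert plans, "expected at least one accepted plan on the fixture"
        for plan in plans:
            bands = sorted(plan.predicted_bands)
            assert bands[0] >= 100
            assert bands[-1] <= 9500
            for a, b in zip(bands, bands[1:]):
                assert b - a >= 0.1 * b
            assert sum(bands) == len(design5.target_sequence)

    def test_ranked_by_band_count_then_gap(self, design5, table):
        plans = select_combinations(design5.target_sequence, table)
        counts = [len(p.predicted_bands) for p in plans]
        assert counts == sorted(counts, reverse=True)


class TestCommonEnzymes:
    def test_batch_of_one_equals_its_accepted_set(self, design5, table):
        seq = design5.target_sequence
        common, per = common_enzymes({"p1": seq}, table)
        assert set(common) == {p.enzymes for p in per["p1"]}

    def test_intersection_across_batch_matches_bruteforce(self, table):
        from agoassembly.fixtures import FixtureSpec, generate_design

        batch = {
            f"p{s}": generate_design(FixtureSpec(n_fragments=3, seed=s)).target_sequence
            for s in (41, 42, 43, 44)
        }
        common, per = common_enzymes(batch, table)
        sets = [{p.enzymes for p in plans} for plans in per.values()]
        assert set(common) == set.intersection(*sets)

    def test_disjoint_sets_give_empty_result_with_fallbacks(self, table):
        # one plasmid with no sites at all vs one normal plasmid
        bare = ("AC" * 3000)
        normal = rand_circle(5, 4000)
        common, per = common_enzymes({"bare": bare, "normal": normal}, table)
        if not {p.enzymes for p in per["bare"]} & {p.enzymes for p in per["normal"]}:
            assert common == []
        assert "bare" in per and "normal" in per


class TestMatchBands:
    def test_exact_match_passes(self):
        assert match_bands([2000, 3000], [2000, 3000]).passed

    def test_within_tolerance_passes(self):
        res = match_bands([2000, 3000], [2100, 2950], tolerance=0.1)
        assert res.passed
        assert res.pairs == [(2000, 2100), (3000, 2950)]

    def test_missing_band_fails_and_is_named(self):
        res = match_bands([2000, 3000], [2000])
        assert not res.passed
        assert res.unmatched_predicted == [3000]

    def test_unexplained_observed_band_fails_unless_below_noise(self):
        assert not match_bands([2000], [2000, 800]).passed
        assert match_bands([2000], [2000, 30]).passed  # sub-noise peak ignored


class TestEnzymeTable:
    def test_packaged_table_loads_30plus_enzymes(self, table):
        assert len(table) >= 30
        assert "EcoRI" in table and table["EcoRI"].site == "GAATTC"

    def test_invalid_iupac_rejected(self):
        with pytest.raises(ValidationError):
            Enzyme("Bad", "GAXTTC", 1, 1)

    def test_custom_tsv_round_trip(self, tmp_path, table):
        p = tmp_path / "enz.tsv"
        p.write_text("name\tsite\tcut_top\tcut_bottom\nTestI\tGANNTC\t2\t2\n")
        t = EnzymeTable.from_tsv(p)
        assert t["TestI"].site == "GANNTC"
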