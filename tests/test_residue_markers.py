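"""Conservation, diagnostic-residue discovery, motifs, nomenclature."""

from collections import Counter

import numpy as np
import pytest

from ap2erf.constants import AP2_SCAFFOLD, ERF_GROUPS, GROUP_MARKERS
from ap2erf.errors import InputError
from ap2erf.phylo_group import NumberedDomain
from ap2erf.residue_markers import (
    column_conservation,
    find_group_markers,
    find_universal_residues,
    map_nomenclature,
    scan_motifs,
    subfamily_call,
)
from ap2erf.synthetic_data import _domain_residues, _residues_seq

UNIVERSAL = {148: "G", 150: "R", 152: "R", 155: "G", 160: "E",
             161: "I", 172: "W", 173: "L", 174: "G", 182: "A"}


def _dom(row: str, gene="g") -> NumberedDomain:
    return NumberedDomain(gene, {145 + i: aa for i, aa in enumerate(row)})


class TestColumnConservation:
    def test_single_sequence_all_frequencies_one(self):
        table = column_conservation([("G1", _dom(AP2_SCAFFOLD))])
        for p in range(145, 203):
            assert table.freq("G1", p) == {AP2_SCAFFOLD[p - 145]: 1.0}

    def test_two_sequences_split_at_one_position(self):
        row2 = "V" + AP2_SCAFFOLD[1:]
        table = column_conservation([("G1", _dom(AP2_SCAFFOLD)), ("G1", _dom(row2))])
        assert table.freq("G1", 145) == {"A": 0.5, "V": 0.5}
        assert table.freq("G1", 146) == {"Y": 1.0}

    def test_matches_brute_force_tally(self, rng):
        rows = ["".join("ACDE"[i] for i in rng.integers(0, 4, 58)) for _ in range(20)]
        labels = ["A" if i % 2 else "B" for i in range(20)]
        table = column_conservation(
            [(lab, _dom(row)) for lab, row in zip(labels, rows)]
        )
        for group in ("A", "B"):
            members = [r for lab, r in zip(labels, rows) if lab == group]
            for p in (145, 160, 202):
                tally = Counter(r[p - 145] for r in members)
                expect = {aa: c / len(members) for aa, c in tally.items()}
                assert table.freq(group, p) == pytest.approx(expect)


class TestUniversalResidues:
    def test_reference_panel_yields_exactly_the_universal_set(self, panel):
        table = column_conservation((d.group, d) for d in panel)
        uni = find_universal_residues(table, 100.0, groups=ERF_GROUPS)
        assert uni == UNIVERSAL

    def test_zero_threshold_reports_all_positions(self, panel):
        table = column_conservation((d.group, d) for d in panel)
        uni = find_universal_residues(table, 0.0, groups=ERF_GROUPS)
        assert set(uni) == set(range(145, 203))

    def test_single_mutated_copy_excludes_position(self, panel):
        mutated = NumberedDomain("mut", {**{145 + i: aa for i, aa in enumerate(AP2_SCAFFOLD)}, 148: "A"})
        table = column_conservation(
            [(d.group, d) for d in panel] + [("I", mutated)]
        )
        uni = find_universal_residues(table, 100.0, groups=ERF_GROUPS)
        assert 148 not in uni
        assert 150 in uni


class TestGroupMarkers:
    def test_panel_reproduces_shipped_marker_set_exactly(self, panel):
        """Discovery recovers every shipped marker: the VI-L pair
        K189+M196, VII's triple I149+G168+V169, the +X167 insertion rule
        for group IX, and the AP2 family's split T150/A150."""
        table = column_conservation((d.group, d) for d in panel)
        got = find_group_markers(table).as_set()
        expect = {(g, p, r) for g, entries in GROUP_MARKERS.items() for p, r in entries}
        assert got == expect

    def test_single_group_reports_conserved_positions(self):
        table = column_conservation([("G1", _dom(AP2_SCAFFOLD)) for _ in range(3)])
        entries = find_group_markers(table).entries
        reported = {(e.position, e.residue) for e in entries}
        assert (148, "G") in reported and (182, "A") in reported

    def test_strict_threshold_drops_discordant_member(self, panel):
        """With within_min=100 a single discordant S175 copy removes the
        group II marker at that position."""
        discordant = _domain_residues(np.random.default_rng(0), "ERF", "II", minor_q=0.0)
        discordant[175] = "A"
        table = column_conservation(
            [(d.group, d) for d in panel] + [("II", NumberedDomain("x", discordant))]
        )
        got = find_group_markers(table, within_min=100.0).as_set()
        assert ("II", 175, "S") not in got
        assert ("II", 176, "Y") in got

    def test_invariant_under_reordering_and_duplication(self, panel):
        table1 = column_conservation((d.group, d) for d in panel)
        base = find_group_markers(table1).as_set()
        reordered = list(reversed(panel)) + [panel[0]]   # duplicate one member
        table2 = column_conservation((d.group, d) for d in reordered)
        assert find_group_markers(table2).as_set() == base


class TestSubfamilyCall:
    @pytest.mark.parametrize(
        "r158,r163,expected",
        [("V", "E", "DREB"), ("A", "D", "ERF"), ("V", "D", "UNRESOLVED")],
    )
    def test_diagnostic_rule(self, r158, r163, expected):
        row = list(AP2_SCAFFOLD)
        row[158 - 145], row[163 - 145] = r158, r163
        assert subfamily_call(_dom("".join(row))) == expected

    def test_agrees_with_sakuma_banding_on_cohort(self, result, truth_by_id):
        from ap2erf.constants import DREB_GROUPS

        for gid, ga in result.assignments.items():
            t = truth_by_id[gid]
            if t.family == "ERF" and t.has_full_domain:
                expected = "DREB" if t.group in DREB_GROUPS else "ERF"
                assert ga.subfamily == expected, gid


class TestScanMotifs:
    def test_scaffold_contains_core_elements(self):
        rep = scan_motifs(AP2_SCAFFOLD)
        assert rep.has("YRG") and rep.has("WLG") and rep.has("RAYD")
        assert not rep.has("KREYD")

    def test_kreyd_only_in_group_vi_l(self, rng):
        vil = _residues_seq(_domain_residues(rng, "ERF", "VI-L", minor_q=0.0))
        gi = _residues_seq(_domain_residues(rng, "ERF", "I", minor_q=0.0))
        assert scan_motifs(vil).has("KREYD")
        assert not scan_motifs(gi).has("KREYD")

    def test_featureless_peptide_has_no_motifs(self):
        rep = scan_motifs("AAAA")
        assert not any(rep.has(m) for m in ("YRG", "WLG", "RAYD", "KREYD", "EAR"))

    def test_ear_pattern(self):
        assert scan_motifs("GGLDLNLAPGG").has("EAR")
        assert scan_motifs("GGLDLNAAPGG").positions["EAR"] is None


class TestNomenclature:
    @pytest.mark.parametrize(
        "family,group,expected",
        [
            ("ERF", "II", ("DREB", "A-1 to A-6")),
            ("ERF", "VI-L", ("ERF", "B-6")),
            ("ERF", "IX", ("ERF", "B-1 to B-6")),
            ("RAV", None, ("RAV", "-")),
            ("SOLOIST", None, ("SOLOIST", "-")),
        ],
    )
    def test_mapping(self, family, group, expected):
        assert map_nomenclature(family, group) == expected

    def test_unknown_group_rejected(self):
        with pytest.raises(InputError, match="unknown"):
            map_nomenclature("ERF", "XIV")
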