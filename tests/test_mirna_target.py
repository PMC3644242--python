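"""miRNA target scanning: penalties, energy model, inhibition, regions."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ap2erf.errors import InputError
from ap2erf.mirna_target import (
    TargetScanParams,
    annotate_site,
    duplex_energy,
    scan_targets,
)

MIR894 = "GUGCGUUUCACGUCGG"
SITE894 = "UUGCCGUGAAACGCAU"   # published target fragment, 5'->3'


def _embed(site_rna: str, flank5="ACGUACGUACGUACGUGGGG", flank3="CCCCAUGCAUGCAUGC"):
    return flank5 + site_rna + flank3


def _revcomp_rna(seq):
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    return "".join(comp[c] for c in reversed(seq))


class TestScanTargets:
    def test_perfect_complement_single_hit_penalty_zero(self):
        target = "ACGUGAUCGAUGGCAUCGAUA"
        hits = scan_targets(_revcomp_rna(target), _embed(target))
        assert len(hits) == 1
        assert hits[0].penalty == 0.0
        assert hits[0].inhibition == "cleavage"

    def test_published_mir894_alignment_scores_2_5(self):
        """One non-pair plus three G:U wobbles over a 16-column alignment:
        penalty 2.5, accepted at the default threshold."""
        hits = scan_targets(MIR894, _embed(SITE894), mirna_id="miR894")
        assert len(hits) == 1
        h = hits[0]
        assert h.penalty == 2.5
        assert len(h.mir_fragment) == 16
        assert h.mir_fragment == MIR894
        assert h.target_fragment == SITE894
        assert h.pairing[10] == "WC" and h.pairing[11] == "WC"
        assert h.energy <= -20.0

    def test_non_pairing_protected_position_rejected(self):
        target = "ACGUGAUCGAUGGCAUCGAUA"
        mir = list(_revcomp_rna(target))
        m = len(mir)
        # break pairing opposite miRNA position 10
        t = target[m - 10]
        mir[9] = {"A": "C", "C": "A", "G": "A", "U": "C"}[t]
        assert scan_targets("".join(mir), _embed(target)) == []

    def test_t_and_u_interchangeable(self):
        target = "ACGUGAUCGAUGGCAUCGAUA"
        mir = _revcomp_rna(target)
        rna_hits = scan_targets(mir, _embed(target))
        dna_hits = scan_targets(
            mir.replace("U", "T"), _embed(target).replace("U", "T")
        )
        assert [(h.interval, h.penalty) for h in rna_hits] == [
            (h.interval, h.penalty) for h in dna_hits
        ]

    def test_gapped_site_found_with_gap_penalty(self):
        target = "ACGUGAUCGAUGGCAUCGAUA"
        mir = _revcomp_rna(target)
        bulged = target[:10] + "C" + target[10:]   # extra target base
        hits = scan_targets(mir, _embed(bulged))
        assert len(hits) == 1
        assert hits[0].penalty == 2.0
        assert "-" in hits[0].mir_fragment

    def test_penalty_monotone_in_mismatches(self):
        target = "ACGUGAUCGAUGGCAUCGAUA"
        mir = _revcomp_rna(target)
        m = len(mir)
        prev = -1.0
        params = TargetScanParams(penalty_threshold=6.0, energy_cutoff=0.0)
        # corrupt positions away from the protected pair one at a time
        for n_bad in range(3):
            mm = list(mir)
            for k in range(n_bad):
                pos = 2 + k            # miRNA positions 2, 3, ...
                t = target[m - pos]
                mm[pos - 1] = {"A": "C", "C": "A", "G": "A", "U": "C"}[t]
            hits = scan_targets("".join(mm), _embed(target), params)
            assert hits, n_bad
            pen = min(h.penalty for h in hits)
            assert pen >= prev
            prev = pen

    def test_invalid_character_rejected(self):
        with pytest.raises(InputError, match="non-RNA"):
            scan_targets("ACGUXACGUACGUACGU", "ACGU" * 20)

    def test_planted_translation_sites_called_translation(self, result):
        planted = {(s.mirna_id, s.gene_id, s.interval): s.mode
                   for s in result.planted_sites if not s.skipped}
        modes = [
            (h.inhibition, planted[(h.mirna_id, h.gene_id, h.interval)])
            for h in result.mirna_hits
            if (h.mirna_id, h.gene_id, h.interval) in planted
        ]
        assert all(got == want for got, want in modes)
        assert any(want == "translation" for _, want in modes)


class TestDuplexEnergy:
    def test_ten_gc_pairs(self):
        assert duplex_energy("G" * 10, "C" * 10) == -30.0

    def test_all_unpaired_is_zero(self):
        assert duplex_energy("AAAA", "CCCC") == 0.0

    def test_wobble_contributes_minus_one(self):
        assert duplex_energy("G", "U") == -1.0

    def test_published_fragments_pass_the_bound(self):
        assert duplex_energy(MIR894, SITE894) <= -20.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError, match="length"):
            duplex_energy("ACG", "AC")


class TestInhibitionRule:
    def test_wobble_at_protected_position_means_translation(self):
        target = list("ACGUGAUCGAUGGCAUCGAUA")
        m = len(target)
        mir = list(_revcomp_rna("".join(target)))
        # make position 10 a G:U wobble: set miRNA base to G opposite U
        if target[m - 10] != "U":
            target[m - 10] = "U"
            mir = list(_revcomp_rna("".join(target)))
        mir[9] = "G"
        hits = scan_targets("".join(mir), _embed("".join(target)))
        assert len(hits) == 1
        assert hits[0].pairing[10] == "wobble"
        assert hits[0].inhibition == "translation"


class TestAnnotateSite:
    @pytest.mark.parametrize(
        "interval,expected",
        [
            ((10, 31), "5'UTR"),
            ((105, 126), "CDS-before-AP2"),
            ((210, 231), "CDS-inside-AP2"),
            ((420, 441), "CDS-after-AP2"),
            ((520, 541), "3'UTR"),
        ],
    )
    def test_region_labels(self, interval, expected):
        assert annotate_site(interval, (100, 500), (200, 374), 600) == expected

    def test_midpoint_decides_straddling_site(self):
        # midpoint inside the domain although the site starts before it
        assert annotate_site((190, 211), (100, 500), (200, 374), 600) == "CDS-inside-AP2"

    def test_site_outside_transcript_rejected(self):
        with pytest.raises(InputError, match="outside transcript"):
            annotate_site((590, 611), (100, 500), None, 600)

    def test_without_domain_interval(self):
        assert annotate_site((210, 231), (100, 500), None, 600) == "CDS"
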