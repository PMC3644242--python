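"""Anchoring, block curation, p-distance, NJ and group assignment."""

import numpy as np
import pytest

from ap2erf.constants import AP2_SCAFFOLD
from ap2erf.errors import InputError
from ap2erf.phylo_group import (
    CuratedBlock,
    NumberedDomain,
    anchor_align,
    assign_group,
    assign_groups,
    extract_block,
    nj_tree,
    pdistance_matrix,
)
from ap2erf.synthetic_data import _domain_residues, _residues_seq

from helpers import random_additive_tree, splits_of_edges, splits_of_treenode


class TestAnchorAlign:
    def test_group_ix_domain_occupies_59_positions(self, ap2_model, rng):
        seq = _residues_seq(_domain_residues(rng, "ERF", "IX", minor_q=0.0))
        nd = anchor_align(seq, ap2_model)
        assert nd.occupied == 59
        assert "167i" in nd.residues

    def test_group_i_domain_occupies_58_positions(self, ap2_model, rng):
        seq = _residues_seq(_domain_residues(rng, "ERF", "I", minor_q=0.0))
        nd = anchor_align(seq, ap2_model)
        assert nd.occupied == 58
        assert "167i" not in nd.residues

    def test_scaffold_maps_identically_with_no_gaps(self, ap2_model):
        nd = anchor_align(AP2_SCAFFOLD, ap2_model)
        assert nd.occupied == 58
        assert all(nd.residues[p] == AP2_SCAFFOLD[p - 145] for p in range(145, 203))

    def test_idempotent_on_anchored_sequence(self, ap2_model, rng):
        seq = _residues_seq(_domain_residues(rng, "ERF", "V", minor_q=0.05))
        first = anchor_align(seq, ap2_model)
        again = anchor_align(first.sequence(), ap2_model)
        assert first.residues == again.residues

    def test_non_domain_sequence_rejected(self, ap2_model, rng):
        junk = "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, 58))
        with pytest.raises(InputError, match="not an AP2 domain"):
            anchor_align(junk, ap2_model)


def _domains_from_rows(rows):
    return [
        NumberedDomain(gene_id=f"s{i}", residues={145 + p: aa for p, aa in enumerate(row)})
        for i, row in enumerate(rows)
    ]


class TestExtractBlock:
    def test_identical_sequences_keep_all_58_columns(self):
        msa = _domains_from_rows([AP2_SCAFFOLD] * 5)
        block = extract_block(msa, conservation_threshold=0.5)
        assert len(block.columns) == 58

    def test_hypervariable_column_is_excluded(self):
        """57 conserved columns plus one hypervariable column curate to a
        57-column block."""
        rows = []
        for i in range(6):
            row = list(AP2_SCAFFOLD)
            row[30] = "ACDEFG"[i]      # one hypervariable column
            rows.append("".join(row))
        block = extract_block(_domains_from_rows(rows), conservation_threshold=0.5)
        assert len(block.columns) == 57
        assert 175 not in block.columns

    def test_alternating_columns_raise(self):
        rows = []
        for i in range(6):
            row = list(AP2_SCAFFOLD)
            for p in range(0, 58, 2):
                row[p] = "ACDEFG"[i]
            rows.append("".join(row))
        with pytest.raises(InputError, match="conserved run"):
            extract_block(_domains_from_rows(rows), min_block=10)


class TestPDistance:
    def test_identical_rows_have_zero_distance(self):
        block = CuratedBlock(["a", "b"], list(range(5)), ["AAAAA", "AAAAA"])
        assert pdistance_matrix(block)[0, 1] == 0.0

    def test_known_fraction(self):
        r1 = AP2_SCAFFOLD[:57]
        r2 = "VVVVV" + r1[5:]
        changed = sum(a != b for a, b in zip(r1, r2))
        block = CuratedBlock(["a", "b"], list(range(57)), [r1, r2])
        assert pdistance_matrix(block)[0, 1] == pytest.approx(changed / 57)

    def test_matches_brute_force_recount(self, rng):
        rows = ["".join("ACDE"[i] for i in rng.integers(0, 4, 40)) for _ in range(8)]
        block = CuratedBlock([f"s{i}" for i in range(8)], list(range(40)), rows)
        D = pdistance_matrix(block)
        for i in range(8):
            for j in range(8):
                brute = sum(a != b for a, b in zip(rows[i], rows[j])) / 40
                assert D[i, j] == pytest.approx(brute)

    def test_no_comparable_columns_raises(self):
        block = CuratedBlock(["a", "b"], list(range(4)), ["AA--", "--CC"])
        with pytest.raises(InputError, match="comparable"):
            pdistance_matrix(block)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        pt = nj_tree(D, ["A", "B", "C"])
        lengths = {t.name: t.length for t in pt.tree.tips()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0}

    def test_four_taxa_additive_topology(self):
        # ((A,B),(C,D)) with internal branch 2
        D = np.array(
            [[0, 2, 5, 5], [2, 0, 5, 5], [5, 5, 0, 2], [5, 5, 2, 0]], float
        )
        pt = nj_tree(D, list("ABCD"))
        names = {0: "A", 1: "B", 2: "C", 3: "D"}
        splits = splits_of_treenode(pt.tree, {v: k for k, v in names.items()})
        assert frozenset({frozenset({0, 1}), frozenset({2, 3})}) in splits

    def test_duplicate_taxon_placed_as_sister(self):
        D = np.array(
            [[0, 0, 4, 6], [0, 0, 4, 6], [4, 4, 0, 6], [6, 6, 6, 0]], float
        )
        pt = nj_tree(D, list("ABCD"))
        a = next(t for t in pt.tree.tips() if t.name == "A")
        sibling_names = {t.name for t in a.parent.tips()} - {"A"}
        assert "B" in sibling_names

    def test_non_symmetric_matrix_rejected(self):
        D = np.array([[0, 1, 2], [1.5, 0, 2], [2, 2, 0]])
        with pytest.raises(InputError, match="symmetric"):
            nj_tree(D, list("ABC"))

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_recovers_generating_topology_on_additive_matrices(self, n):
        rng = np.random.default_rng(n)
        for _ in range(20):
            edges, D = random_additive_tree(rng, n)
            pt = nj_tree(D, [str(i) for i in range(n)])
            got = splits_of_treenode(pt.tree, {str(i): i for i in range(n)})
            assert got == splits_of_edges(edges, n)

    def test_agrees_with_skbio_nj_on_random_additive_matrices(self):
        """Independent cross-check against scikit-bio's NJ."""
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(123)
        for _ in range(10):
            _, D = random_additive_tree(rng, 6)
            ids = [str(i) for i in range(6)]
            mine = nj_tree(D, ids).tree
            theirs = skbio_nj(DistanceMatrix(D, ids))
            mapping = {str(i): i for i in range(6)}
            assert splits_of_treenode(mine, mapping) == splits_of_treenode(theirs, mapping)


class TestAssignGroup:
    def test_group_vii_query_assigned_group_vii(self, panel, rng):
        seq_res = _domain_residues(rng, "ERF", "VII", minor_q=0.05)
        ga = assign_group(NumberedDomain("q", seq_res), panel)
        assert ga.group == "VII"

    def test_query_identical_to_reference_gets_its_group(self, panel):
        ref = next(r for r in panel if r.group == "III")
        ga = assign_group(NumberedDomain("q", dict(ref.residues)), panel)
        assert ga.group == "III"

    def test_invariant_under_reference_reordering(self, panel, rng):
        res = _domain_residues(rng, "ERF", "X", minor_q=0.05)
        q = NumberedDomain("q", res)
        shuffled = list(panel)
        rng.shuffle(shuffled)
        assert assign_group(q, panel).group == assign_group(q, shuffled).group

    def test_cohort_group_recovery_is_complete(self, result, truth_by_id):
        """100% group recovery for full-domain ERF genes."""
        checked = 0
        for gid, ga in result.assignments.items():
            t = truth_by_id[gid]
            if t.has_full_domain and t.family == "ERF":
                assert ga.group == t.group, gid
                checked += 1
        assert checked == 115

    def test_missing_reference_group_warns(self, panel, rng):
        res = _domain_residues(rng, "ERF", "I", minor_q=0.0)
        subset = [r for r in panel if r.group not in ("X",)]
        with pytest.warns(UserWarning, match="missing groups"):
            ga = assign_groups([NumberedDomain("q", res)], subset)[0]
        assert ga.group == "I"
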