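"""Read counting, group aggregation, tissue shares and qPCR ratios."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ap2erf.errors import InputError
from ap2erf.tissue_expression import (
    QpcrMeasurement,
    aggregate_by_group,
    count_reads,
    qpcr_ratio,
    tissue_percentages,
)

# Published group x tissue read counts (bark, embryo, latex, leaf, root)
GROUP_READS = {
    "I": [189, 101, 108, 38, 393],
    "II": [25, 16, 99, 47, 26],
    "III": [60, 28, 5, 14, 41],
    "IV": [21, 10, 20, 3, 39],
    "V": [3, 7, 3, 1, 19],
    "VI": [3, 4, 2, 1, 19],
    "VI-L": [73, 25, 19, 14, 52],
    "VII": [683, 516, 737, 171, 954],
    "VIII": [126, 150, 219, 200, 137],
    "IX": [112, 29, 14, 101, 112],
    "X": [21, 31, 3, 12, 33],
}
LIBS = ["bark", "embryo", "latex", "leaf", "root"]


class TestCountReads:
    def test_empty_input_gives_empty_matrix(self):
        rm = count_reads([])
        assert rm.matrix.empty

    def test_rows_for_same_cell_are_summed(self):
        rm = count_reads([("c1", "latex", 2), ("c1", "latex", 3), ("c1", "bark", 1)])
        assert rm.matrix.loc["c1", "latex"] == 5
        assert rm.matrix.loc["c1", "bark"] == 1

    def test_per_read_layout_counts_rows(self):
        rm = count_reads([("c1", "r1", "latex"), ("c1", "r2", "latex"), ("c2", "r3", "bark")])
        assert rm.matrix.loc["c1", "latex"] == 2
        assert rm.matrix.loc["c2", "bark"] == 1

    def test_negative_count_rejected(self):
        with pytest.raises(InputError, match="negative"):
            count_reads([("c1", "latex", -1)])

    def test_unknown_library_rejected(self):
        with pytest.raises(InputError, match="unknown library"):
            count_reads([("c1", "petal", 3)], libraries=["latex"])

    def test_matrix_matches_generator_truth(self, result):
        rm = count_reads(result.membership, libraries=list(result.config.tissues))
        for t in result.truths:
            for lib, v in t.tissue_counts.items():
                assert rm.matrix.loc[t.gene_id, lib] == v


class TestAggregateByGroup:
    def _printed_matrix(self):
        rows, assignments = [], {}
        for g, counts in GROUP_READS.items():
            for lib, v in zip(LIBS, counts):
                rows.append((f"contig_{g}", lib, v))
            assignments[f"contig_{g}"] = g
        return count_reads(rows, libraries=LIBS), assignments

    def test_published_cells_reproduce_published_margins(self):
        """Row total 829 for group I, bark column total 1316, grand 5889."""
        rm, assignments = self._printed_matrix()
        table = aggregate_by_group(rm, assignments, row_order=list(GROUP_READS))
        assert table.loc["I", "Total"] == 829
        assert table.loc["Total", "bark"] == 1316
        assert table.loc["Total", "Total"] == 5889

    def test_all_zero_matrix_gives_zero_table(self):
        rm = count_reads([("c1", "latex", 0), ("c2", "bark", 0)])
        table = aggregate_by_group(rm, {"c1": "I", "c2": "II"})
        assert table.to_numpy().sum() == 0

    def test_invariant_under_contig_permutation(self):
        rm, assignments = self._printed_matrix()
        rows = []
        for g in reversed(list(GROUP_READS)):
            for lib, v in zip(LIBS, GROUP_READS[g]):
                rows.append((f"contig_{g}", lib, v))
        rm2 = count_reads(rows, libraries=LIBS)
        t1 = aggregate_by_group(rm, assignments, row_order=list(GROUP_READS))
        t2 = aggregate_by_group(rm2, assignments, row_order=list(GROUP_READS))
        assert t1.equals(t2)

    def test_margins_conserved_under_partition_refinement(self, result):
        """Group-table cells sum to the same grand total as the raw matrix."""
        rm = count_reads(result.membership, libraries=list(result.config.tissues))
        table = result.group_table
        assert table.loc["Total", "Total"] == rm.total


class TestTissuePercentages:
    def test_published_read_counts_give_published_shares(self):
        counts = {"root": 1883, "bark": 1403, "latex": 1341,
                  "embryogenic": 1037, "leaf": 654}
        shares = tissue_percentages(counts)
        assert shares == {"root": 29.8, "bark": 22.2, "latex": 21.2,
                          "embryogenic": 16.4, "leaf": 10.4}

    def test_single_tissue_is_100(self):
        assert tissue_percentages({"latex": 7}) == {"latex": 100.0}

    def test_zero_total_rejected(self):
        with pytest.raises(InputError, match="> 0"):
            tissue_percentages({"latex": 0})

    @given(
        counts=st.lists(st.integers(min_value=1, max_value=10_000),
                        min_size=2, max_size=6),
        k=st.integers(min_value=2, max_value=50),
    )
    def test_scale_invariance(self, counts, k):
        base = {f"t{i}": v for i, v in enumerate(counts)}
        scaled = {lib: v * k for lib, v in base.items()}
        assert tissue_percentages(base) == tissue_percentages(scaled)

    def test_shares_sum_to_about_100(self, result):
        assert sum(result.tissue_shares.values()) == pytest.approx(100.0, abs=0.3)


class TestQpcr:
    @pytest.mark.parametrize(
        "cp_t,cp_r,expected", [(20.0, 20.0, 1.0), (21.0, 20.0, 0.5), (18.0, 20.0, 4.0)]
    )
    def test_closed_form_identities(self, cp_t, cp_r, expected):
        m = QpcrMeasurement("s", "g", cp_t, cp_r)
        assert qpcr_ratio(m) == pytest.approx(expected)

    @given(
        cp_t=st.floats(min_value=5, max_value=40),
        delta=st.floats(min_value=0.1, max_value=5),
    )
    def test_monotone_in_cp_values(self, cp_t, delta):
        lo = qpcr_ratio(QpcrMeasurement("s", "g", cp_t + delta, 20.0))
        hi = qpcr_ratio(QpcrMeasurement("s", "g", cp_t, 20.0))
        assert lo < hi
        up = qpcr_ratio(QpcrMeasurement("s", "g", 20.0, cp_t + delta))
        dn = qpcr_ratio(QpcrMeasurement("s", "g", 20.0, cp_t))
        assert up > dn

    def test_efficiency_correction(self):
        m = QpcrMeasurement("s", "g", 21.0, 20.0,
                            efficiency_target=1.9, efficiency_reference=2.0)
        assert qpcr_ratio(m) == pytest.approx(1.9 ** -21 / 2.0 ** -20)

    def test_validation(self):
        with pytest.raises(InputError, match="cp_target"):
            QpcrMeasurement("s", "g", 0.0, 20.0)
        with pytest.raises(InputError, match="efficiency_target"):
            QpcrMeasurement("s", "g", 20.0, 20.0, efficiency_target=2.5)
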