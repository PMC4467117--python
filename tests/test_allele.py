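import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prrkit.allele import (
    AlleleCounts,
    allele_fraction,
    ddct_expression,
    expression_table,
    fisher_allele_test,
    percent_input,
    read_ct_table,
    scale_areas,
)

from conftest import enumerate_fisher_p


class TestAlleleFraction:
    @pytest.mark.parametrize(
        "a,g,expected", [(50, 50, 50.0), (0, 100, 0.0), (632, 368, 63.2)]
    )
    def test_printed_formula(self, a, g, expected):
        assert allele_fraction(AlleleCounts("s", a, g)) == pytest.approx(expected)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            allele_fraction(AlleleCounts("s", 0, 0))

    @given(a=st.integers(0, 10_000), g=st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_complements_sum_to_100(self, a, g):
        if a + g == 0:
            return
        f1 = allele_fraction(AlleleCounts("x", a, g))
        f2 = allele_fraction(AlleleCounts("x", g, a))
        assert f1 + f2 == pytest.approx(100.0)

    def test_non_integer_units_rejected(self):
        with pytest.raises(TypeError, match="scale"):
            AlleleCounts("s", 10.5, 3)

    def test_scale_areas_rounds(self):
        c = scale_areas("s", 63.24, 36.76, scale=10)
        assert (c.units_a, c.units_g) == (632, 368)


class TestFisher:
    def test_balanced_table_p_one(self):
        res = fisher_allele_test(AlleleCounts("input", 5, 5), AlleleCounts("chip", 5, 5))
        assert res.p_value == pytest.approx(1.0)
        assert res.odds_ratio == pytest.approx(1.0)

    def test_diagonal_table_exact_value(self):
        # 2 extreme tables out of C(20,10)=184756 equally-likely orderings
        res = fisher_allele_test(AlleleCounts("input", 10, 0), AlleleCounts("chip", 0, 10))
        assert res.p_value == pytest.approx(2 / 184756, rel=1e-9)

    def test_single_count_diagonal(self):
        res = fisher_allele_test(AlleleCounts("input", 1, 0), AlleleCounts("chip", 0, 1))
        assert res.p_value == pytest.approx(1.0)

    def test_zero_cell_odds_ratio_inf(self):
        res = fisher_allele_test(AlleleCounts("input", 10, 1), AlleleCounts("chip", 0, 10))
        # oratio = a*d/(b*c) with c=0 -> +inf, no exception
        assert math.isinf(res.odds_ratio)

    def test_fractions_reported_per_sample(self):
        res = fisher_allele_test(AlleleCounts("input", 632, 368), AlleleCounts("chip", 850, 150))
        assert res.fraction_a_pct["input"] == pytest.approx(63.2)
        assert res.fraction_a_pct["chip"] == pytest.approx(85.0)

    def test_zero_row_total_rejected(self):
        with pytest.raises(ValueError):
            fisher_allele_test(AlleleCounts("input", 0, 0), AlleleCounts("chip", 5, 5))

    def test_row_and_column_swap_invariance(self):
        base = fisher_allele_test(AlleleCounts("i", 8, 3), AlleleCounts("c", 2, 9))
        rows = fisher_allele_test(AlleleCounts("i", 2, 9), AlleleCounts("c", 8, 3))
        cols = fisher_allele_test(AlleleCounts("i", 3, 8), AlleleCounts("c", 9, 2))
        assert base.p_value == pytest.approx(rows.p_value, rel=1e-12)
        assert base.p_value == pytest.approx(cols.p_value, rel=1e-12)

    def test_p_decreases_as_table_grows_extreme(self):
        # fixed margins 20/20, shift mass to the diagonal
        ps = [
            fisher_allele_test(AlleleCounts("i", 10 + k, 10 - k),
                               AlleleCounts("c", 10 - k, 10 + k)).p_value
            for k in range(0, 11, 2)
        ]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    @given(
        a=st.integers(0, 15), b=st.integers(0, 15),
        c=st.integers(0, 15), d=st.integers(0, 15),
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_enumeration_oracle(self, a, b, c, d):
        if a + b == 0 or c + d == 0:
            return
        res = fisher_allele_test(AlleleCounts("i", a, b), AlleleCounts("c", c, d))
        assert res.p_value == pytest.approx(enumerate_fisher_p(a, b, c, d), abs=1e-10)

    @given(
        a=st.integers(0, 25), b=st.integers(0, 25),
        c=st.integers(0, 25), d=st.integers(0, 25),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_scipy_implementation(self, a, b, c, d):
        """Cross-check against an independent mature implementation."""
        from scipy import stats

        if a + b == 0 or c + d == 0:
            return
        res = fisher_allele_test(AlleleCounts("i", a, b), AlleleCounts("c", c, d))
        _, p_scipy = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        assert res.p_value == pytest.approx(p_scipy, abs=1e-9)


def ct_frame(rows):
    return pd.DataFrame(rows, columns=["gene", "condition", "replicate", "ct"])


class TestDdct:
    def test_identical_cts_fold_one(self):
        rows = [
            (g, c, 1, 22.0)
            for g in ("T", "GAPDH", "B2M") for c in ("ctrl", "treated")
        ]
        fold = ddct_expression(ct_frame(rows), "T", ["GAPDH", "B2M"], "treated", "ctrl")
        assert fold == pytest.approx(1.0)

    def test_one_cycle_shift_doubles(self):
        rows = [("T", "ctrl", 1, 25.0), ("T", "treated", 1, 24.0),
                ("GAPDH", "ctrl", 1, 20.0), ("GAPDH", "treated", 1, 20.0)]
        fold = ddct_expression(ct_frame(rows), "T", ["GAPDH"], "treated", "ctrl")
        assert fold == pytest.approx(2.0)

    def test_two_reference_genes_arithmetic_mean(self):
        rows = [("GAPDH", c, 1, 20.0) for c in ("ctrl", "treated")]
        rows += [("B2M", c, 1, 22.0) for c in ("ctrl", "treated")]
        rows += [("T", "ctrl", 1, 25.0), ("T", "treated", 1, 24.0)]
        fold = ddct_expression(ct_frame(rows), "T", ["GAPDH", "B2M"], "treated", "ctrl")
        assert fold == pytest.approx(2.0)  # ref mean 21 both; ddCt = -1

    def test_global_ct_shift_invariant(self):
        rows = [("T", "ctrl", 1, 25.0), ("T", "treated", 1, 23.5),
                ("GAPDH", "ctrl", 1, 20.0), ("GAPDH", "treated", 1, 20.2)]
        base = ddct_expression(ct_frame(rows), "T", ["GAPDH"], "treated", "ctrl")
        shifted = ct_frame([(g, c, r, ct + 5.0) for g, c, r, ct in rows])
        assert ddct_expression(shifted, "T", ["GAPDH"], "treated", "ctrl") == pytest.approx(base)

    def test_replicates_averaged(self):
        rows = [("T", "ctrl", 1, 25.0), ("T", "ctrl", 2, 27.0),
                ("T", "treated", 1, 24.0), ("T", "treated", 2, 26.0),
                ("GAPDH", "ctrl", 1, 20.0), ("GAPDH", "treated", 1, 20.0)]
        fold = ddct_expression(ct_frame(rows), "T", ["GAPDH"], "treated", "ctrl")
        assert fold == pytest.approx(2.0)

    def test_missing_combination_rejected(self):
        rows = [("T", "ctrl", 1, 25.0), ("GAPDH", "ctrl", 1, 20.0)]
        with pytest.raises(ValueError, match="treated"):
            ddct_expression(ct_frame(rows), "T", ["GAPDH"], "treated", "ctrl")

    def test_expression_table_all_conditions(self):
        rows = [("T", "ctrl", 1, 25.0), ("T", "treated", 1, 23.0),
                ("GAPDH", "ctrl", 1, 20.0), ("GAPDH", "treated", 1, 20.0)]
        table = expression_table(ct_frame(rows), ["T"], ["GAPDH"], "ctrl")
        by_cond = dict(zip(table["condition"], table["fold_change"]))
        assert by_cond["ctrl"] == pytest.approx(1.0)
        assert by_cond["treated"] == pytest.approx(4.0)


def chip_ct(rows):
    return pd.DataFrame(rows, columns=["condition", "sample", "ct"])


class TestPercentInput:
    def test_equal_adjusted_cts_give_100(self):
        # input 10% -> adjusted input Ct = Ct + log2(10)
        rows = [("EtOH", "input", 20.0), ("EtOH", "chip", 20.0 + math.log2(10))]
        out = percent_input(chip_ct(rows), 0.10, "EtOH")
        assert out["percent_input"].iloc[0] == pytest.approx(100.0)
        assert out["relative"].iloc[0] == pytest.approx(1.0)

    def test_closed_form_example(self):
        rows = [("EtOH", "input", 20.0), ("EtOH", "chip", 23.3219)]
        out = percent_input(chip_ct(rows), 0.10, "EtOH")
        assert out["percent_input"].iloc[0] == pytest.approx(100.0, rel=1e-4)

    def test_relative_to_control(self):
        rows = [("EtOH", "input", 20.0), ("EtOH", "chip", 25.0),
                ("DHT", "input", 20.0), ("DHT", "chip", 23.0)]
        out = percent_input(chip_ct(rows), 0.10, "EtOH").set_index("condition")
        assert out.loc["EtOH", "relative"] == pytest.approx(1.0)
        assert out.loc["DHT", "relative"] == pytest.approx(4.0)  # 2 cycles

    @pytest.mark.parametrize("frac", [0.0, -0.1, 1.5])
    def test_bad_input_fraction_rejected(self, frac):
        rows = [("EtOH", "input", 20.0), ("EtOH", "chip", 22.0)]
        with pytest.raises(ValueError, match="input_fraction"):
            percent_input(chip_ct(rows), frac, "EtOH")

    def test_missing_control_rejected(self):
        rows = [("DHT", "input", 20.0), ("DHT", "chip", 22.0)]
        with pytest.raises(ValueError, match="control"):
            percent_input(chip_ct(rows), 0.1, "EtOH")


class TestReadCtTable:
    def test_valid_roundtrip(self, tmp_path):
        path = tmp_path / "ct.tsv"
        ct_frame([("T", "ctrl", 1, 25.0)]).to_csv(path, sep="\t", index=False)
        df = read_ct_table(path)
        assert df["ct"].iloc[0] == 25.0

    def test_nonpositive_ct_rejected(self, tmp_path):
        path = tmp_path / "ct.tsv"
        ct_frame([("T", "ctrl", 1, -3.0)]).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="finite"):
            read_ct_table(path)
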