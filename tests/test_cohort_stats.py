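"""Rate tables: the half-up percentage primitive and the cohort cross-tabs."""

import math
from fractions import Fraction

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from karyocohort import (
    classify_cohort,
    category_rates,
    level1_table,
    pair_counts,
    rate,
    unbalanced_by_indication,
)


class TestRate:
    @pytest.mark.parametrize(
        "count, denom, expected",
        [(353, 38636, 0.91), (0, 100, 0.00), (47, 38636, 0.12), (690, 1663, 41.49),
         (100, 100, 100.00), (1, 3, 33.33), (2, 3, 66.67), (1, 8, 12.5), (5, 1000, 0.5)],
    )
    def test_examples(self, count, denom, expected):
        assert rate(count, denom) == expected

    def test_half_up_not_bankers(self):
        # 0.125% rounds up to 0.13, not to even
        assert rate(1, 800) == 0.13

    def test_zero_denominator_is_an_error(self):
        with pytest.raises(ZeroDivisionError):
            rate(0, 0)

    def test_count_out_of_range(self):
        with pytest.raises(ValueError):
            rate(5, 4)

    @given(count=st.integers(0, 50_000), denom=st.integers(1, 50_000))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_matches_exact_fraction_oracle(self, count, denom):
        """Oracle: round-half-up via exact rational arithmetic."""
        count = min(count, denom)
        expected = math.floor(Fraction(count * 10_000, denom) + Fraction(1, 2)) / 100
        assert rate(count, denom) == expected


class TestLevel1Table:
    def test_all_normals(self):
        df = pd.DataFrame({"year": [2019] * 100, "level1": ["normal"] * 100})
        table = level1_table(df)
        by_class = table.set_index("level1")["percent"]
        assert by_class["normal"] == 100.00
        assert by_class["mosaic"] == 0.00 == by_class["non_mosaic"] == by_class["polymorphism"]

    def test_one_of_each_class(self):
        df = pd.DataFrame({
            "year": [2019] * 4,
            "level1": ["mosaic", "non_mosaic", "polymorphism", "normal"],
        })
        table = level1_table(df)
        assert set(table["percent"]) == {25.00}
        assert table["count"].sum() == table["denominator"].iloc[0]

    def test_partition_sums_to_100(self, small_classified):
        table = level1_table(small_classified)
        assert abs(table["percent"].sum() - 100.0) <= 0.02
        assert table["count"].sum() == len(small_classified)

    def test_by_year_partitions_each_year(self, small_classified):
        table = level1_table(small_classified, by_year=True)
        for _, sub in table.groupby("year"):
            assert abs(sub["percent"].sum() - 100.0) <= 0.02
            assert sub["count"].sum() == sub["denominator"].iloc[0]

    def test_percent_recomputes_from_own_row(self, small_classified):
        table = level1_table(small_classified, by_year=True)
        for row in table.itertuples():
            assert row.percent == rate(row.count, row.denominator)

    def test_row_order_invariance(self, small_classified):
        shuffled = small_classified.sample(frac=1, random_state=0)
        a = level1_table(small_classified).sort_values("level1", ignore_index=True)
        b = level1_table(shuffled).sort_values("level1", ignore_index=True)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_cohort_fails(self):
        with pytest.raises(ValueError):
            level1_table(pd.DataFrame({"level1": []}))


class TestCategoryRates:
    def test_within_stratum_shares(self):
        df = classify_cohort(pd.DataFrame({"karyotype": [
            "mos 45,X[5]/46,XX[25]", "mos 45,X[7]/46,XX[13]",
            "47,XX,+21", "47,XY,+21",
        ]}))
        table = category_rates(df, "aneuploidy", stratify_by_level1=True)
        mosaic_x = table.query("level1 == 'mosaic' and chromosome == 'X'")
        assert mosaic_x["percent"].iloc[0] == 100.00
        nm_21 = table.query("level1 == 'non_mosaic' and chromosome == '21'")
        assert nm_21["percent"].iloc[0] == 100.00

    def test_unstratified_uses_cohort_denominator(self):
        df = classify_cohort(pd.DataFrame({"karyotype": ["47,XX,+21"] + ["46,XY"] * 99}))
        table = category_rates(df, "aneuploidy")
        assert table["denominator"].iloc[0] == 100
        assert table["percent"].iloc[0] == 1.00

    def test_unknown_label_fails(self, small_classified):
        with pytest.raises(ValueError):
            category_rates(small_classified, "no_such_label")

    def test_empty_subset_yields_zero_rows(self):
        df = classify_cohort(pd.DataFrame({"karyotype": ["46,XY"] * 5}))
        assert category_rates(df, "robertsonian").empty


class TestPairCounts:
    def test_three_rob_13_14(self):
        pairs, multi = pair_counts(["45,XX,rob(13;14)(q10;q10)"] * 3, "robertsonian")
        assert pairs == {("13", "14"): 3}
        assert multi == 0

    def test_unordered(self):
        pairs, _ = pair_counts(
            ["46,XX,t(11;22)(q23;q11)", "46,XY,t(22;11)(q11;q23)"],
            "reciprocal_translocation",
        )
        assert pairs == {("11", "22"): 2}

    def test_three_way_contributes_each_pair_and_is_flagged(self):
        pairs, multi = pair_counts(["46,XY,t(1;3;5)(q21;p13;q22)"], "reciprocal_translocation")
        assert pairs == {("1", "3"): 1, ("1", "5"): 1, ("3", "5"): 1}
        assert multi == 1

    def test_der_notation_counts_as_robertsonian(self):
        pairs, _ = pair_counts(["45,XX,der(13;14)(q10;q10)"], "robertsonian")
        assert pairs == {("13", "14"): 1}

    def test_invalid_kind(self):
        with pytest.raises(ValueError):
            pair_counts([], "inversion")

    def test_matches_string_scan_oracle(self, small_classified):
        """Oracle: regex scan of the raw strings for rob( / der(a;b) tokens."""
        import re

        expected: dict[tuple[str, str], int] = {}
        for s in small_classified["karyotype"]:
            for m in re.finditer(r"(?:rob|der)\((\d+);(\d+)\)\(q10;q10\)", s):
                pair = tuple(sorted(m.groups(), key=int))
                expected[pair] = expected.get(pair, 0) + 1
        pairs, _ = pair_counts(small_classified["karyotype"], "robertsonian")
        assert pairs == expected


class TestUnbalancedByIndication:
    def test_small_crosstab(self):
        df = pd.DataFrame({
            "primary_indication": ["high_risk_NIPT"] * 10 + ["others"] * 5,
            "level4": ["unbalanced"] * 4 + ["balanced"] * 6 + ["balanced"] * 5,
        })
        table = unbalanced_by_indication(df)
        nipt = table.set_index("primary_indication").loc["high_risk_NIPT"]
        assert nipt["percent"] == 40.00
        assert table.set_index("primary_indication").loc["others", "percent"] == 0.00

    def test_absent_group_omitted(self):
        df = pd.DataFrame({"primary_indication": ["others"], "level4": ["balanced"]})
        table = unbalanced_by_indication(df)
        assert list(table["primary_indication"]) == ["others"]

    def test_matches_bruteforce_crosstab(self, small_classified):
        from karyocohort import add_indications

        df = add_indications(small_classified)
        table = unbalanced_by_indication(df).set_index("primary_indication")
        for ind in df["primary_indication"].unique():
            sub = df[df["primary_indication"] == ind]
            assert table.loc[ind, "count"] == (sub["level4"] == "unbalanced").sum()
            assert table.loc[ind, "denominator"] == len(sub)
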