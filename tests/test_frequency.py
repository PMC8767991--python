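"""Frequency matrices: counting semantics, marginals, top-k, rollup, and
equivalence with a brute-force per-record recount."""

import numpy as np
import pandas as pd
import pytest

from icdvar import (
    PartitionSpec,
    StratumFilter,
    build_matrix,
    filter_coded,
    marginal_totals,
    rollup,
    top_k,
)
from icdvar.frequency import FrequencyMatrix, Partition
from icdvar.visits import assign_age_group
from icdvar import reference

from conftest import make_visits


def naive_matrix(visits, level, partitions, hierarchy, stratum=StratumFilter()):
    """Independent per-record recount: plain Python loops, no pandas."""
    counts = {p.name: {} for p in partitions}
    for row in visits.itertuples(index=False):
        if stratum.modality and row.modality != stratum.modality:
            continue
        if stratum.specialty and row.specialty != stratum.specialty:
            continue
        if stratum.sex and row.sex != stratum.sex:
            continue
        if stratum.age_group and assign_age_group(row.age) != stratum.age_group:
            continue
        name = None
        for p in partitions:
            if p.start <= row.date < p.end:
                name = p.name
        if name is None or not row.codes:
            continue
        for code in row.codes.split(";"):
            key = hierarchy.group_key(code[:3], level)
            counts[name][key] = counts[name].get(key, 0) + 1
    return counts


def as_dicts(matrix):
    return {
        part: {g: int(n) for g, n in row.items() if n}
        for part, row in matrix.counts.iterrows()
    }


class TestBuildMatrix:
    def test_one_visit_two_codes_counts_two_occurrences(self, hierarchy, years):
        df = make_visits([("2019-03-01", "face_to_face", "nursing", "male", 50, "I10;E11")])
        m = build_matrix(df, 2, years, hierarchy)
        assert as_dicts(m)["Y2019"] == {"I10-I16": 1, "E08-E13": 1}

    def test_duplicate_code_counts_twice_by_default(self, hierarchy, years):
        df = make_visits([("2019-03-01", "face_to_face", "nursing", "male", 50, "I10;I10")])
        m = build_matrix(df, 2, years, hierarchy)
        assert as_dicts(m)["Y2019"] == {"I10-I16": 2}
        m2 = build_matrix(df, 2, years, hierarchy, dedupe_per_visit=True)
        assert as_dicts(m2)["Y2019"] == {"I10-I16": 1}

    def test_row_totals_equal_code_occurrences(self, cohort_100k, hierarchy, years):
        coded, _ = filter_coded(cohort_100k)
        m = build_matrix(coded, 1, years, hierarchy)
        per_visit = coded["codes"].str.count(";") + 1
        assert m.row_totals().sum() + m.n_outside == per_visit.sum()

    def test_visits_outside_partitions_counted_not_absorbed(self, hierarchy):
        df = make_visits([
            ("2019-03-01", "face_to_face", "nursing", "male", 50, "I10"),
            ("2022-03-01", "face_to_face", "nursing", "male", 50, "I10;E11"),
        ])
        m = build_matrix(df, 1, PartitionSpec.years(2019), hierarchy)
        assert m.n_outside == 2
        assert m.grand_total() == 1

    def test_empty_input_gives_zero_matrix(self, hierarchy, years):
        df = make_visits([]).astype({"date": "datetime64[ns]"})
        m = build_matrix(df, 1, years, hierarchy)
        assert m.grand_total() == 0
        assert m.partitions == ["Y2019", "Y2020"]

    @pytest.mark.parametrize("level", [1, 2, 3])
    @pytest.mark.parametrize(
        "stratum",
        [StratumFilter(), StratumFilter(modality="telemedicine"),
         StratumFilter(specialty="nursing", sex="female"),
         StratumFilter(age_group="older_adult")],
    )
    def test_oracle_equivalence_on_small_cohort(self, cohort_1k, hierarchy, years,
                                                level, stratum):
        coded, _ = filter_coded(cohort_1k)
        m = build_matrix(coded, level, years, hierarchy, stratum)
        assert as_dicts(m) == naive_matrix(coded, level, years, hierarchy, stratum)

    def test_stratum_additivity(self, cohort_1k, hierarchy, years):
        coded, _ = filter_coded(cohort_1k)
        full = build_matrix(coded, 1, years, hierarchy)
        f2f = build_matrix(coded, 1, years, hierarchy, StratumFilter(modality="face_to_face"))
        tele = build_matrix(coded, 1, years, hierarchy, StratumFilter(modality="telemedicine"))
        summed = f2f.counts.add(tele.counts, fill_value=0).astype(int)
        pd.testing.assert_frame_equal(
            summed[full.counts.columns], full.counts, check_names=False)


class TestLevelConsistency:
    def test_rollup_reproduces_coarser_levels_exactly(self, cohort_100k, hierarchy, years):
        coded, _ = filter_coded(cohort_100k)
        m3 = build_matrix(coded, 3, years, hierarchy)
        m2 = build_matrix(coded, 2, years, hierarchy)
        m1 = build_matrix(coded, 1, years, hierarchy)
        r2 = rollup(m3, hierarchy, 2)
        r1 = rollup(m2, hierarchy, 1)
        pd.testing.assert_frame_equal(r2.counts[m2.groups], m2.counts, check_names=False)
        pd.testing.assert_frame_equal(r1.counts[m1.groups], m1.counts, check_names=False)
        assert r2.counts.to_numpy().sum() == m3.counts.to_numpy().sum()


class TestMarginals:
    def test_reference_grand_total_and_share(self):
        m = reference.chapter_matrix()
        marg = marginal_totals(m)
        assert m.grand_total() == 3_921_974
        assert marg.loc["Z00-Z99", "total"] == 483_368
        assert marg.loc["Z00-Z99", "share_pct"] == pytest.approx(12.32, abs=0.005)

    def test_single_column_share_is_100(self, hierarchy, years):
        df = make_visits([("2019-03-01", "face_to_face", "nursing", "male", 50, "I10")])
        m = build_matrix(df, 1, years, hierarchy)
        assert marginal_totals(m)["share_pct"].iloc[0] == 100.0


class TestTopK:
    def test_reference_top5_over_half(self):
        t = top_k(reference.chapter_matrix(), 5)
        assert list(t.index) == ["Z00-Z99", "E00-E89", "I00-I99", "M00-M99", "R00-R99"]
        assert t["cumulative_pct"].iloc[-1] > 50.0
        assert t["cumulative_pct"].is_monotonic_increasing

    def test_k_exceeding_columns_returns_all(self):
        t = top_k(reference.chapter_matrix(), 1000)
        assert len(t) == 21
        assert t["cumulative_pct"].iloc[-1] == pytest.approx(100.0)

    def test_equal_counts_tie_broken_lexicographically(self):
        counts = pd.DataFrame({"B00-B09": [3, 0], "A00-A09": [2, 1]},
                              index=["Y2019", "Y2020"])
        m = FrequencyMatrix(counts=counts, level=2)
        t = top_k(m, 2)
        assert list(t.index) == ["A00-A09", "B00-B09"]


class TestPartitionSpec:
    def test_overlapping_partitions_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            PartitionSpec((
                Partition("a", pd.Timestamp("2019-01-01"), pd.Timestamp("2019-07-01")),
                Partition("b", pd.Timestamp("2019-06-01"), pd.Timestamp("2020-01-01")),
            ))

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            PartitionSpec((
                Partition("a", pd.Timestamp("2019-01-01"), pd.Timestamp("2019-02-01")),
                Partition("a", pd.Timestamp("2019-03-01"), pd.Timestamp("2019-04-01")),
            ))

    def test_serialization_roundtrip(self, tmp_path, hierarchy, years, cohort_1k):
        coded, _ = filter_coded(cohort_1k)
        m = build_matrix(coded, 1, years, hierarchy)
        path = tmp_path / "matrix.tsv"
        m.to_tsv(path)
        back = pd.read_csv(path, sep="\t", index_col="group")
        assert (back.drop(columns="total").T.to_numpy() == m.counts.to_numpy()).all()
        assert path.with_suffix(".tsv.meta.yaml").exists()
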