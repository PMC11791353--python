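"""Paired FF/FFPE overlap, recurrence frequencies, paired tests."""

import math

import numpy as np
import pytest
from scipy import stats as sp_stats

from fusionskew.cohort_concordance import (
    build_patient_pairs,
    library_comparison,
    pair_overlap,
    paired_mean_test,
    percent_of,
    rank_correlation,
    recurrence_table,
    summarize_cohort,
)
from fusionskew.coverage import LibraryStats

from conftest import make_record


class TestPairOverlap:
    def test_partial_overlap(self):
        result = pair_overlap({"A", "B"}, {"B", "C"})
        assert result.shared == {"B"}
        assert result.ff_only == {"A"}
        assert result.ffpe_only == {"C"}
        assert result.jaccard == pytest.approx(1 / 3)

    def test_identical_sets(self):
        assert pair_overlap({"A", "B"}, {"A", "B"}).jaccard == 1.0

    def test_disjoint_sets(self):
        result = pair_overlap({"A"}, {"B"})
        assert result.shared == set()
        assert result.jaccard == 0.0

    def test_both_empty(self):
        assert pair_overlap(set(), set()).jaccard == 0.0

    def test_partition_counts_add_up(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            ff = set(rng.choice(20, rng.integers(0, 10), replace=False).tolist())
            ffpe = set(rng.choice(20, rng.integers(0, 10), replace=False).tolist())
            result = pair_overlap(ff, ffpe)
            assert len(result.shared) + len(result.ff_only) == len(ff)
            assert len(result.shared) + len(result.ffpe_only) == len(ffpe)


class TestRecurrence:
    @pytest.mark.parametrize(
        "count, total, expected",
        [(20, 29, 69), (17, 29, 59), (13, 29, 45), (10, 29, 34), (7, 29, 24),
         (5, 29, 17), (3, 29, 10), (19, 112, 17), (93, 112, 83)],
    )
    def test_percent_rounding_half_away_from_zero(self, count, total, expected):
        assert percent_of(count, total) == expected

    def test_table_counts_patients_once_and_sorts(self):
        mapping = {
            f"P{i:02d}": {("KANSL1", "ARL17A")} if i <= 20 else set() for i in range(1, 30)
        }
        mapping["P01"].add(("MACC1", "AC005062.1"))
        mapping["P02"].add(("MACC1", "AC005062.1"))
        table = recurrence_table(mapping, n_patients=29)
        top = table.iloc[0]
        assert top["fusion"] == "KANSL1--ARL17A"
        assert top["n_patients"] == 20
        assert top["percent"] == 69
        assert table.iloc[1]["percent"] == percent_of(2, 29)
        assert table["recurrent"].all()

    def test_percent_self_consistency(self):
        rng = np.random.default_rng(6)
        mapping = {
            f"P{i}": {("G%d" % g, "H") for g in rng.choice(15, rng.integers(0, 6), replace=False)}
            for i in range(25)
        }
        table = recurrence_table(mapping, n_patients=25)
        for _, row in table.iterrows():
            assert row["percent"] == percent_of(row["n_patients"], 25)

    def test_empty_mapping(self):
        assert recurrence_table({}, n_patients=5).empty


class TestPairedMeanTest:
    def test_identical_vectors(self):
        result = paired_mean_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert result.t == 0.0
        assert result.p == 1.0
        assert result.degenerate

    def test_constant_nonzero_difference_is_degenerate(self):
        result = paired_mean_test([1, 2, 3, 4], [2, 3, 4, 5])
        assert result.degenerate
        assert result.mean_difference == -1.0

    def test_matches_textbook_closed_form(self):
        x = [3.0, 5.0, 4.0, 6.0, 7.0]
        y = [2.0, 6.0, 2.0, 5.0, 9.0]
        result = paired_mean_test(x, y)
        diff = np.array(x) - np.array(y)
        t_expected = diff.mean() / (diff.std(ddof=1) / math.sqrt(len(diff)))
        p_expected = 2 * sp_stats.t.sf(abs(t_expected), df=len(diff) - 1)
        assert result.t == pytest.approx(t_expected, abs=1e-10)
        assert result.p == pytest.approx(p_expected, abs=1e-10)

    def test_agrees_with_scipy_ttest_rel(self):
        rng = np.random.default_rng(8)
        x = rng.normal(10, 2, 12)
        y = rng.normal(9, 2, 12)
        result = paired_mean_test(x, y)
        ref = sp_stats.ttest_rel(x, y)
        assert result.t == pytest.approx(ref.statistic, abs=1e-10)
        assert result.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_equals_one_sample_test_on_differences(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=10), rng.normal(size=10)
        result = paired_mean_test(x, y)
        ref = sp_stats.ttest_1samp(x - y, 0.0)
        assert result.t == pytest.approx(ref.statistic, abs=1e-10)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            paired_mean_test([1, 2], [3, 4])


class TestRankCorrelation:
    def test_monotone_and_reversed(self):
        assert rank_correlation([1, 2, 3, 4], [10, 20, 30, 40]).rho == pytest.approx(1.0)
        assert rank_correlation([1, 2, 3, 4], [9, 7, 5, 3]).rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_brute_force(self):
        rng = np.random.default_rng(10)
        x, y = rng.normal(size=10), rng.normal(size=10)
        result = rank_correlation(x, y)
        rx, ry = sp_stats.rankdata(x), sp_stats.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert result.rho == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_flagged_undefined(self):
        result = rank_correlation([1, 1, 1], [1, 2, 3])
        assert not result.defined
        assert math.isnan(result.rho)


class TestLibraryComparison:
    @staticmethod
    def _cohort(ff_insert=206.0, ffpe_insert=186.0, ff_reads=15_000_000, ffpe_reads=30_000_000, n=6):
        stats = []
        for i in range(n):
            pid = f"P{i:02d}"
            stats.append(LibraryStats(f"{pid}_FF", "FF", ff_reads, ff_insert, patient_id=pid))
            stats.append(LibraryStats(f"{pid}_FFPE", "FFPE", ffpe_reads, ffpe_insert, patient_id=pid))
        return stats

    def test_insert_median_difference(self):
        frame = library_comparison(self._cohort()).set_index("metric")
        row = frame.loc["median_insert_size"]
        assert row["ff_median"] == 206.0
        assert row["ffpe_median"] == 186.0
        assert row["median_difference"] == 20.0

    def test_coverage_ratio(self):
        frame = library_comparison(self._cohort()).set_index("metric")
        assert frame.loc["uniquely_mapped_reads"]["ffpe_over_ff_ratio"] == pytest.approx(2.0)

    def test_identical_groups_give_p_one(self):
        frame = library_comparison(self._cohort(ffpe_insert=206.0, ffpe_reads=15_000_000))
        assert (frame["mean_difference"] == 0).all()
        assert (frame["p"] == 1.0).all()

    def test_unpaired_patient_excluded_with_warning(self):
        stats = self._cohort()
        stats.append(LibraryStats("P99_FF", "FF", 1000, 200.0, patient_id="P99"))
        with pytest.warns(UserWarning, match="P99"):
            frame = library_comparison(stats)
        assert (frame["n_pairs"] == 6).all()


class TestBuildPairsAndSummary:
    def test_patient_pairs_from_records_with_alias(self):
        records = [
            make_record("KANSL1", "ARL17A", sample_id="P01_FF", patient_id="P01", material="FF"),
            make_record("KANSL1", "ARL17B", sample_id="P01_FFPE", patient_id="P01", material="FFPE"),
            make_record("TFG", "ADGRG7", sample_id="P02_FF", patient_id="P02", material="FF"),
        ]
        alias = {"ARL17A": "ARL17", "ARL17B": "ARL17"}
        pairs = build_patient_pairs(records, alias)
        assert [p.patient_id for p in pairs] == ["P01", "P02"]
        # the two ARL17 paralog variants collapse to one shared key
        assert pairs[0].overlap.shared == {("KANSL1", "ARL17")}
        assert pairs[1].ffpe_fusions == set()

    def test_summarize_cohort_shared_count(self):
        records = []
        for i in range(1, 6):
            pid = f"P{i:02d}"
            records.append(make_record("A", "B", sample_id=f"{pid}_FF", patient_id=pid, material="FF"))
            if i <= 3:  # 3 of 5 patients share in both materials
                records.append(
                    make_record("A", "B", sample_id=f"{pid}_FFPE", patient_id=pid, material="FFPE")
                )
        summary = summarize_cohort(build_patient_pairs(records))
        assert summary.n_patients == 5
        assert summary.n_patients_with_shared == 3
        assert summary.recurrence.iloc[0]["n_patients"] == 5
        assert summary.recurrence.iloc[0]["percent"] == 100
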