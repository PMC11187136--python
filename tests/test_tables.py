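"""Count-table validation, filtering, rarefaction and dyad matching."""

import numpy as np
import pandas as pd
import pytest

from matneo import tables
from matneo.tables import (
    CountTable,
    CountTableError,
    DuplicateIdError,
    MetadataMismatchError,
    NonIntegerCountError,
    cohort_summary,
    filter_samples,
    filter_taxa,
    load_counts,
    match_dyad_samples,
    rarefy,
    relative_abundance,
    round_half_up,
    write_counts,
)

from conftest import make_count_table


class TestValidationAndIO:
    def test_roundtrip_write_read(self, toy_table, tmp_path):
        cp, mp = tmp_path / "c.tsv", tmp_path / "m.tsv"
        write_counts(toy_table, cp, mp)
        back = load_counts(cp, mp)
        pd.testing.assert_frame_equal(back.counts, toy_table.counts)
        assert list(back.meta.index) == list(toy_table.meta.index)

    def test_two_by_two_values(self, tmp_path):
        (tmp_path / "c.tsv").write_text("taxon_id\ts1\ts2\nt1\t1\t2\nt2\t3\t4\n")
        (tmp_path / "m.tsv").write_text(
            "sample_id\tsubject_id\trole\tsite\tday\tcollection_time\n"
            "s1\td1\tneonate\tbuccal\t1\t1.0\ns2\td2\tneonate\tbuccal\t1\t2.0\n"
        )
        t = load_counts(tmp_path / "c.tsv", tmp_path / "m.tsv")
        assert t.counts.to_numpy().tolist() == [[1, 2], [3, 4]]

    def test_fractional_count_rejected(self, tmp_path):
        (tmp_path / "c.tsv").write_text("taxon_id\ts1\nt1\t3.5\n")
        (tmp_path / "m.tsv").write_text(
            "sample_id\tsubject_id\trole\tsite\tday\tcollection_time\ns1\td1\tneonate\tbuccal\t1\t1.0\n"
        )
        with pytest.raises(NonIntegerCountError):
            load_counts(tmp_path / "c.tsv", tmp_path / "m.tsv")

    def test_duplicate_and_mismatch_errors(self, toy_table):
        dup = toy_table.counts.copy()
        dup.index = ["a", "a", "b"]
        with pytest.raises(DuplicateIdError):
            CountTable(dup, toy_table.meta)
        with pytest.raises(MetadataMismatchError):
            CountTable(toy_table.counts, toy_table.meta.iloc[:2])

    def test_negative_count_rejected(self, toy_table):
        bad = toy_table.counts.copy()
        bad.iloc[0, 0] = -1
        with pytest.raises(CountTableError):
            CountTable(bad, toy_table.meta)


class TestFilterSamples:
    def test_threshold_inclusive_at_5000(self):
        t = make_count_table([[5000, 6000, 100]])
        kept = filter_samples(t, min_reads=5000)
        assert kept.n_samples == 2
        assert set(kept.sample_ids) == {"sample_0", "sample_1"}

    def test_identity_cases(self, toy_table):
        assert filter_samples(toy_table, min_reads=0).n_samples == toy_table.n_samples

    def test_empty_result_warns(self, toy_table):
        with pytest.warns(UserWarning):
            out = filter_samples(toy_table, min_reads=10**9)
        assert out.n_samples == 0


class TestFilterTaxa:
    def test_all_zero_taxon_removed(self):
        t = make_count_table(np.vstack([np.zeros(20, int), np.full(20, 100)]))
        out = filter_taxa(t)
        assert "taxon_0" not in out.taxon_ids

    def test_abundant_taxon_kept(self):
        # 0.2% relative abundance in 10% of 20 samples
        counts = np.zeros((2, 20), int)
        counts[1] = 1000
        counts[0, :2] = 2  # 2/1002 = 0.1996%... push above 0.1%: 2/1002 > 0.001
        t = make_count_table(counts)
        out = filter_taxa(t)
        assert "taxon_0" in out.taxon_ids

    def test_boundary_prevalence_strict(self):
        # 1 read in exactly 15% of samples and < 0.1% abundance -> removed
        counts = np.zeros((2, 20), int)
        counts[1] = 5000
        counts[0, :3] = 1  # 3/20 = 15% exactly; 1/5001 < 0.1%
        t = make_count_table(counts)
        out = filter_taxa(t)
        assert "taxon_0" not in out.taxon_ids

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        t = make_count_table(rng.integers(0, 50, size=(30, 25)))
        once = filter_taxa(t)
        twice = filter_taxa(once)
        pd.testing.assert_frame_equal(once.counts, twice.counts)


class TestRarefy:
    def test_exact_depth_unchanged(self):
        t = make_count_table([[30], [70]])
        out = rarefy(t, depth=100, seed=1)
        assert out.counts["sample_0"].tolist() == [30, 70]

    def test_column_sums_equal_depth_and_zero_support(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 500, size=(15, 6))
        counts[4] = 0
        t = make_count_table(counts)
        out = rarefy(t, depth=int(counts.sum(axis=0).min()), seed=0)
        depth = int(counts.sum(axis=0).min())
        assert (out.totals() == depth).all()
        assert (out.counts.loc["taxon_4"] == 0).all()

    def test_hypergeometric_mean(self):
        # expected rarefied count = depth * original proportion
        t = make_count_table([[300], [700]])
        depth = 100
        draws = np.array(
            [rarefy(t, depth=depth, seed=s).counts.iloc[0, 0] for s in range(1000)]
        )
        # hypergeometric mean 30, var n*p*q*(N-n)/(N-1) = 100*.3*.7*(900/999)
        se = np.sqrt(depth * 0.3 * 0.7 * (1000 - depth) / (1000 - 1) / len(draws))
        assert abs(draws.mean() - 30.0) < 3 * se

    def test_shallow_sample_error_names_sample(self):
        t = make_count_table([[10, 5000], [10, 5000]])
        with pytest.raises(CountTableError, match="sample_0"):
            rarefy(t, depth=100)


class TestRelativeAbundance:
    def test_basic_and_scaling_invariance(self):
        t = make_count_table([[2], [2]])
        assert relative_abundance(t)["sample_0"].tolist() == [0.5, 0.5]
        t2 = make_count_table([[20], [20]])
        pd.testing.assert_frame_equal(relative_abundance(t), relative_abundance(t2))

    def test_zero_total_error(self):
        t = make_count_table([[0, 1], [0, 1]])
        with pytest.raises(CountTableError):
            relative_abundance(t)


class TestMatchDyadSamples:
    def _table(self, rows):
        # rows: (sample_id, subject, role, day, time)
        n = len(rows)
        meta = pd.DataFrame(
            {
                "subject_id": [r[1] for r in rows],
                "role": [r[2] for r in rows],
                "site": "buccal",
                "day": [r[3] for r in rows],
                "collection_time": [r[4] for r in rows],
            },
            index=[r[0] for r in rows],
        )
        counts = pd.DataFrame(
            np.ones((2, n), int), index=["t1", "t2"], columns=[r[0] for r in rows]
        )
        return CountTable(counts, meta)

    def test_day1_preferred_over_day2(self):
        t = self._table(
            [
                ("a", "d1", "neonate", "0", 5.0),
                ("b", "d1", "neonate", "1", 30.0),
                ("c", "d1", "neonate", "2", 50.0),
            ]
        )
        out = match_dyad_samples(t)
        slots = out.meta.set_index(out.meta.index)["slot"]
        assert slots["b"] == "day1or2" and "c" not in slots.index

    def test_day2_fallback(self):
        t = self._table(
            [("a", "d1", "neonate", "0", 5.0), ("c", "d1", "neonate", "2", 50.0)]
        )
        out = match_dyad_samples(t)
        assert out.meta.loc["c", "slot"] == "day1or2"

    def test_first_day0_and_last_prenatal(self):
        t = self._table(
            [
                ("m1", "d1", "mother", "prenatal", 200.0),
                ("m2", "d1", "mother", "prenatal", 240.0),
                ("n1", "d1", "neonate", "0", 3.0),
                ("n2", "d1", "neonate", "0", 8.0),
            ]
        )
        out = match_dyad_samples(t)
        assert out.meta.loc["m2", "slot"] == "maternal"
        assert out.meta.loc["n1", "slot"] == "day0"
        assert "m1" not in out.meta.index and "n2" not in out.meta.index

    def test_collection_time_tie_breaks_by_sample_id(self):
        t = self._table(
            [("z", "d1", "neonate", "0", 5.0), ("a", "d1", "neonate", "0", 5.0)]
        )
        out = match_dyad_samples(t)
        assert list(out.meta.index) == ["a"]


class TestCohortSummary:
    @pytest.mark.parametrize(
        "count,denom,expected",
        [(28, 164, 17.1), (136, 164, 82.9), (111, 164, 67.7), (43, 164, 26.2),
         (17, 164, 10.4), (0, 164, 0.0)],
    )
    def test_percentages(self, count, denom, expected):
        out = cohort_summary({"level": count}, denominator=denom)
        assert out.loc["level", "percent"] == expected

    def test_from_series(self):
        s = pd.Series(["yes"] * 17 + ["no"] * 139 + ["unknown"] * 8)
        out = cohort_summary(s)
        assert out.loc["yes", "percent"] == 10.4
        assert out["count"].sum() == 164

    def test_round_half_up(self):
        assert round_half_up(0.05, 1) == 0.1
        assert round_half_up(17.07, 1) == 17.1
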