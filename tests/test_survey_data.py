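"""Data model: ICD chapter assignment, categorical collapsing, quintile
binning, and the CSV round trip."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mtoburden.survey_data import (CHAPTERS, MISSING_CHAPTER, ChapterError,
                                   SchemaError, assign_icd_chapter,
                                   bin_income_quintiles, categorize,
                                   filter_disease_profile, household_size_class,
                                   load_survey, los_class, quintiles)
from mtoburden.synthetic_survey import write_survey


class TestChapterAssignment:
    @pytest.mark.parametrize("code,start,eligible", [
        ("I25", "I00", True),     # circulatory
        ("Z34", "Z00", False),    # excluded from disease profile
        ("M17", "M00", True),     # musculoskeletal
        ("C50", "C00", True),
        ("D49", "C00", True),     # gap code falls to preceding chapter
        ("H60", "H60", True),     # ear, not eye
        ("T98", "S00", True),
        ("a09", "A00", True),     # case-insensitive
    ])
    def test_assignment(self, code, start, eligible):
        ch = assign_icd_chapter(code)
        assert ch.code_start == start
        assert ch.profile_eligible is eligible

    def test_missing_is_sentinel_not_error(self):
        assert assign_icd_chapter(None) is MISSING_CHAPTER
        assert assign_icd_chapter("  ") is MISSING_CHAPTER

    def test_unparseable_raises(self):
        with pytest.raises(ChapterError):
            assign_icd_chapter("9X")

    def test_twenty_two_chapters_partition(self):
        assert len(CHAPTERS) == 22
        assert sum(not c.profile_eligible for c in CHAPTERS) == 1
        # every letter block maps somewhere, and starts are strictly ordered
        starts = [c.code_start for c in CHAPTERS]
        assert starts == sorted(starts)
        for letter in "ABCDEFGHIJKLMNOPQRSTUVWXYZ":
            ch = assign_icd_chapter(f"{letter}50")
            assert ch in CHAPTERS

    def test_total_and_unique_on_all_codes(self):
        # total function on the full letter+2-digit space, one chapter each
        for letter in "ACDEGHIKMNOQRSTUVZ":
            for num in (0, 48, 59, 95, 99):
                ch = assign_icd_chapter(f"{letter}{num:02d}")
                assert ch.profile_eligible is (letter != "Z")


class TestFilterDiseaseProfile:
    def test_omits_z_and_missing(self, survey_records):
        kept, omitted = filter_disease_profile(survey_records)
        assert len(kept) + omitted == len(survey_records)
        assert all(assign_icd_chapter(r.icd_code).profile_eligible for r in kept)
        assert omitted > 0

    def test_identity_when_no_z(self, survey_records):
        eligible = [r for r in survey_records
                    if assign_icd_chapter(r.icd_code).profile_eligible]
        kept, omitted = filter_disease_profile(eligible)
        assert kept == eligible and omitted == 0

    def test_all_z_warns_and_empties(self, survey_records):
        z_only = [r for r in survey_records if (r.icd_code or "").startswith("Z")][:5]
        with pytest.warns(UserWarning):
            kept, omitted = filter_disease_profile(z_only)
        assert kept == [] and omitted == len(z_only)


class TestCategorize:
    def test_table_labels(self, survey_records):
        r = survey_records[0]
        labels = categorize(r)
        assert set(labels) == {"age_group", "household_size_class", "los_class", "region"}

    @pytest.mark.parametrize("age,label", [
        (9, "Children <=9 yrs"), (45, "Adult 30-59 yrs"), (60, "Elderly >=60 yrs"),
    ])
    def test_age_groups(self, age, label, survey_records):
        from dataclasses import replace
        assert categorize(replace(survey_records[0], age=age))["age_group"] == label

    @pytest.mark.parametrize("size,label", [
        (5, "Small (<=5 members)"), (7, "Medium (6-10 members)"), (11, "Large (>10 members)"),
    ])
    def test_household_size_partition(self, size, label):
        assert household_size_class(size) == label

    def test_day_to_stay_class_table(self):
        # hand-written day-to-class table for 0-45 days
        expected = {}
        for d in range(46):
            if d <= 7:
                expected[d] = "<=1 week"
            elif d <= 14:
                expected[d] = "2 weeks"
            elif d <= 21:
                expected[d] = "3 weeks"
            elif d <= 31:
                expected[d] = "1 month"
            else:
                expected[d] = ">1 month"
        assert {d: los_class(d) for d in range(46)} == expected
        assert los_class(10) == "2 weeks"


class TestQuintiles:
    def test_forced_pattern(self):
        assert list(quintiles(list(range(1, 11)))) == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]

    def test_all_equal_warns_quintile_one(self):
        with pytest.warns(UserWarning):
            q = quintiles([7.0] * 20)
        assert set(q) == {1}

    def test_continuous_draws_balanced(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(0, 1, 1000)
        q = quintiles(x)
        counts = np.bincount(q)[1:]
        assert list(counts) == [200] * 5  # continuous, no ties
        # oracle: sort-and-slice gives the same groups
        order = np.argsort(x)
        expected = np.empty(1000, dtype=int)
        expected[order] = np.repeat(np.arange(1, 6), 200)
        assert np.array_equal(q, expected)

    @given(st.lists(st.integers(0, 10_000), min_size=5, max_size=60))
    def test_monotone_in_income(self, incomes):
        q = quintiles(incomes)
        pairs = sorted(zip(incomes, q))
        assert all(q1 <= q2 for (_, q1), (_, q2) in zip(pairs, pairs[1:]))

    def test_record_annotation(self, survey_records):
        q = bin_income_quintiles(survey_records)
        assert set(q.values()) <= {1, 2, 3, 4, 5}
        assert len(q) == len(survey_records)


class TestCsvInterface:
    def test_roundtrip_bit_exact(self, survey_records, tmp_path):
        path = tmp_path / "survey.csv"
        write_survey(survey_records, path)
        result = load_survey(path)
        assert result.n_rows == len(survey_records)
        assert result.errors == []
        assert result.records == list(survey_records)

    def test_stratum_counts(self, survey_records, tmp_path):
        path = tmp_path / "survey.csv"
        write_survey(survey_records, path)
        result = load_survey(path)
        assert len(result.records) == 815
        assert sum(r.stratum == "subsidized" for r in result.records) == 344

    def test_empty_file_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_survey([], path)
        assert len(path.read_text().splitlines()) == 1
        result = load_survey(path)
        assert result.records == [] and result.errors == []

    def test_negative_money_collected_not_dropped_silently(self, survey_records, tmp_path):
        path = tmp_path / "bad.csv"
        write_survey(survey_records[:3], path)
        text = path.read_text().splitlines()
        row = text[1].split(",")
        idx = text[0].split(",").index("household_income_month")
        row[idx] = "-5"
        path.write_text("\n".join([text[0], ",".join(row)] + text[2:]) + "\n")
        result = load_survey(path)
        assert len(result.records) == 2
        assert len(result.errors) == 1
        assert "household_income_month" in result.errors[0][1]

    def test_missing_column_names_it(self, survey_records, tmp_path):
        path = tmp_path / "cut.csv"
        write_survey(survey_records[:2], path)
        lines = path.read_text().splitlines()
        # drop the icd_code column entirely
        cols = lines[0].split(",")
        drop = cols.index("icd_code")
        out = ["\n".join(",".join(v for i, v in enumerate(l.split(",")) if i != drop)
                         for l in lines)]
        path.write_text(out[0])
        with pytest.raises(SchemaError, match="icd_code"):
            load_survey(path)
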