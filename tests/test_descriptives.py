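"""Cohort descriptive summaries: counts, proportions, onset bins, years."""

import datetime as dt
from collections import Counter

import pytest

from faerspv.descriptives import (annual_counts, demographics_summary,
                                  time_to_onset_bins)
from faerspv.io import Occupation, Sex
from faerspv.published import descriptive_fixture

from conftest import make_demo, make_drug, make_outc


class TestDemographicsSummary:
    def test_published_margins_reproduce_printed_proportions(self):
        demo, outc, _ = descriptive_fixture()
        s = demographics_summary(demo, outc)
        sex = s.blocks["sex"]
        assert (sex["male"].proportion, sex["female"].proportion,
                sex["unknown"].proportion) == (0.52, 0.25, 0.23)
        assert s.blocks["reporter"]["consumer"].percent == 58.38
        assert s.blocks["outcome"]["HO"].percent == 23.78
        assert s.blocks["outcome"]["OT"].percent == 17.30
        # alternative denominator: known-outcome cases only
        assert s.blocks["outcome"]["HO"].proportion_known == 0.44

    def test_single_male_case(self):
        s = demographics_summary([make_demo(sex=Sex.MALE)])
        assert s.blocks["sex"]["male"].proportion == 1.00
        assert s.blocks["sex"]["female"].count == 0

    def test_empty_cohort_all_zero(self):
        s = demographics_summary([])
        assert s.cohort_size == 0
        assert all(stat.count == 0
                   for cats in s.blocks.values() for stat in cats.values())

    def test_twenty_case_fixture_matches_brute_force_tally(self):
        sexes = [Sex.MALE] * 7 + [Sex.FEMALE] * 9 + [Sex.UNKNOWN] * 4
        ages = [10.0] * 2 + [30.0] * 5 + [80.0] * 6 + [None] * 7
        demo = [make_demo(f"R{i}", sex=sexes[i], age=ages[i]) for i in range(20)]
        s = demographics_summary(demo)
        assert {k: v.count for k, v in s.blocks["sex"].items()} == Counter(
            x.value for x in sexes)
        assert {k: v.count for k, v in s.blocks["age"].items()} == {
            "<18": 2, "18-65": 5, ">65": 6, "unknown": 7}

    def test_outcome_precedence_one_code_per_case(self):
        demo = [make_demo("R1")]
        outc = [make_outc("R1", "HO"), make_outc("R1", "DE"), make_outc("R1", "OT")]
        s = demographics_summary(demo, outc)
        assert s.blocks["outcome"]["DE"].count == 1
        assert s.blocks["outcome"]["HO"].count == 0

    def test_age_unit_conversion(self):
        import dataclasses
        rec = dataclasses.replace(make_demo("R1", age=700.0), age_unit="MON")
        s = demographics_summary([rec])
        assert s.blocks["age"]["18-65"].count == 1  # 700 months ~ 58 years

    def test_blocks_sum_to_cohort_size(self):
        demo, outc, _ = descriptive_fixture()
        s = demographics_summary(demo, outc)
        for cats in s.blocks.values():
            assert sum(stat.count for stat in cats.values()) == s.cohort_size


class TestTimeToOnset:
    def test_one_gap_per_bin(self, day):
        gaps = [3, 10, 45, 100, None]
        demo, drugs = [], []
        for i, g in enumerate(gaps):
            rid = f"R{i}"
            demo.append(make_demo(rid, event=day(200) if g is not None else None))
            drugs.append(make_drug(rid, start=day(200 - g) if g is not None else None))
        tto = time_to_onset_bins(demo, drugs)
        assert tto.counts == {"<7": 1, "7-28": 1, "28-60": 1, ">60": 1, "unknown": 1}
        assert tto.negative_gaps == 0

    def test_boundary_days(self, day):
        # 0 and 6 -> <7; 7 and 28 -> 7-28; 29 and 60 -> 28-60; 61 -> >60
        gaps = [0, 6, 7, 28, 29, 60, 61]
        demo = [make_demo(f"R{i}", event=day(100)) for i in range(len(gaps))]
        drugs = [make_drug(f"R{i}", start=day(100 - g)) for i, g in enumerate(gaps)]
        tto = time_to_onset_bins(demo, drugs)
        assert tto.counts == {"<7": 2, "7-28": 2, "28-60": 2, ">60": 1, "unknown": 0}

    def test_all_dates_missing_goes_unknown(self):
        demo = [make_demo(f"R{i}") for i in range(4)]
        tto = time_to_onset_bins(demo, [])
        assert tto.counts["unknown"] == 4

    def test_negative_gap_is_unknown_and_warned(self, day):
        demo = [make_demo("R1", event=day(10))]
        drugs = [make_drug("R1", start=day(20))]
        tto = time_to_onset_bins(demo, drugs)
        assert tto.counts["unknown"] == 1
        assert tto.negative_gaps == 1

    def test_published_margins_fixture(self):
        demo, _, drugs = descriptive_fixture()
        tto = time_to_onset_bins(demo, drugs)
        assert tto.counts == {"<7": 2, "7-28": 8, "28-60": 6, ">60": 9,
                              "unknown": 160}
        assert sum(tto.counts.values()) == len(demo)


class TestAnnualCounts:
    def test_empty_cohort(self):
        assert annual_counts([]) == {}

    def test_peak_year(self):
        demo = [make_demo(f"R{i}", received=dt.date(2015, 1, 1)) for i in range(3)]
        demo.append(make_demo("R9", received=dt.date(2016, 3, 1)))
        counts = annual_counts(demo)
        assert counts == {2015: 3, 2016: 1}
        assert max(counts, key=counts.get) == 2015

    def test_generated_dataset_matches_group_by(self):
        from faerspv.io import TableKind, parse_ascii_table
        from faerspv.synthetic import SyntheticConfig, generate_tables

        tables = generate_tables(SyntheticConfig(n_reports=5000, seed=21))
        demo = parse_ascii_table(tables.demo, TableKind.DEMO)
        expected = Counter(
            d.received_date.year if d.received_date else "unknown" for d in demo)
        assert annual_counts(demo) == dict(expected)
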