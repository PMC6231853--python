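"""Descriptive analyses: printed-ratio arithmetic, tables, retention, boxes."""

import numpy as np
import pytest

from siteless.analysis import (demographic_table, funnel_summary,
                               medication_table, pct, preference_summary,
                               quartiles, retention_curve,
                               rom_pain_association)
from siteless.records import FunnelCounts, RomMeasurement, RomSession
from siteless.joints import JointPainMap
from siteless.simulate import CohortConfig, generate_cohort

from conftest import make_record


class TestPct:
    @pytest.mark.parametrize("num,den,dec,expected", [
        (344, 393, 1, 87.5),
        (1018, 1170, 2, 87.01),
        (399, 1170, 2, 34.10),
        (0, 10, 1, 0.0),
        (1, 8, 1, 12.5),      # exact half -> rounds up, not to even
        (45, 399, 1, 11.3),
    ])
    def test_half_up_rounding(self, num, den, dec, expected):
        assert pct(num, den, dec) == expected

    def test_errors(self):
        with pytest.raises(ValueError):
            pct(1, 0)
        with pytest.raises(ValueError):
            pct(5, 4)
        with pytest.raises(ValueError):
            pct(-1, 4)


class TestFunnel:
    def test_study_counts(self):
        counts = FunnelCounts(downloads=1170, consented=428,
                              consented_outside_window=29, enrolled=399)
        df = funnel_summary(counts).set_index("stage")
        assert df.loc["enrolled", "pct_of_downloads"] == 34.10
        assert df.loc["downloads", "n"] == 1170

    def test_degenerate_all_enrolled(self):
        counts = FunnelCounts(downloads=50, consented=50,
                              consented_outside_window=0, enrolled=50)
        df = funnel_summary(counts)
        wanted = df[df.stage != "consented_outside_window"]
        assert set(wanted.pct_of_downloads) == {100.0}

    def test_synthetic_funnel_matches_recount(self):
        records, funnel = generate_cohort(CohortConfig(n_downloads=200, seed=1))
        assert funnel.enrolled == len(records)


class TestTables:
    def test_demographic_cells_hand_computed(self):
        recs = [
            make_record("a", group="A", sex="female", age=40, bmi=20,
                        smoking="never"),
            make_record("b", group="B", sex="male", age=50, bmi=30,
                        smoking="current"),
        ]
        df = demographic_table(recs)
        total = df[df.group == "Total"].set_index(["variable", "category"])
        assert total.loc[("sex", "female"), "n"] == 1
        assert total.loc[("sex", "female"), "pct"] == 50.0
        assert total.loc[("age", ""), "mean"] == 45.0
        # sd of {40, 50} = 7.0711
        assert total.loc[("age", ""), "sd"] == pytest.approx(7.07, abs=0.01)

    def test_single_record_is_100_percent(self):
        df = demographic_table([make_record()])
        cats = df[(df.group == "Total") & df.pct.notna()]
        assert set(cats.pct) == {100.0}

    def test_category_counts_match_brute_tally(self):
        records, _ = generate_cohort(CohortConfig(n_downloads=200, seed=7))
        df = demographic_table(records)
        sub = df[(df.group == "A") & (df.variable == "ethnicity")]
        for row in sub.itertuples():
            expected = sum(1 for r in records if r.group == "A"
                           and r.demographics.ethnicity == row.category)
            assert row.n == expected
        # group counts conserve: A + B = Total for every categorical row
        piv = df[df.pct.notna()].pivot_table(
            index=["variable", "category"], columns="group", values="n")
        assert (piv["A"].fillna(0) + piv["B"].fillna(0) == piv["Total"]).all()

    def test_medication_denominator_drops_with_nonresponse(self):
        answered = [make_record(f"a{i}", medications=["methotrexate"])
                    for i in range(30)]
        skipped = [make_record(f"s{i}", medications=None) for i in range(11)]
        df = medication_table(answered + skipped)
        total = df[df.group == "Total"].set_index("medication")
        assert total.loc["_respondents", "n"] == 30
        assert total.loc["methotrexate", "n"] == 30
        assert total.loc["methotrexate", "pct"] == 100.0


class TestRetention:
    def test_everyone_quits_after_week_1(self):
        recs = [make_record(f"p{i}", last_active=1) for i in range(5)]
        df = retention_curve(recs)
        total = df[df.group == "Total"].set_index("week")
        assert total.loc[1, "fraction"] == 1.0
        assert total.loc[2, "fraction"] == 0.0

    def test_study_marginals_reproduced(self, study_marginal_records):
        df = retention_curve(study_marginal_records)
        total = df[df.group == "Total"].set_index("week")
        assert total.loc[2, "retained"] == 162
        assert total.loc[2, "pct"] == 40.6
        assert total.loc[12, "retained"] == 45
        assert total.loc[12, "pct"] == 11.3
        by_arm = df.set_index(["group", "week"])
        assert by_arm.loc[("A", 12), "pct"] == 13.2
        assert by_arm.loc[("B", 12), "pct"] == 9.4

    def test_monotone_and_matches_brute_recount(self):
        records, _ = generate_cohort(CohortConfig(n_downloads=200, seed=3))
        df = retention_curve(records)
        for group in ("A", "B", "Total"):
            sub = df[df.group == group].sort_values("week")
            assert (np.diff(sub.fraction) <= 1e-12).all()
        total = df[df.group == "Total"].set_index("week")
        for week in range(1, 13):
            expected = sum(1 for r in records if r.last_active_week >= week)
            assert total.loc[week, "retained"] == expected


class TestRomPainAssociation:
    def test_quartile_convention(self):
        q1, med, q3 = quartiles(range(1, 9))
        assert (q1, q3) == (2.75, 6.25)
        assert med == 4.5

    def test_single_group_five_number_summary(self):
        recs = []
        for i, rom in enumerate([100.0, 110.0, 120.0]):
            session = RomSession(week=1, side="right", true_flexion=55,
                                 true_extension=55, trace_seed=i,
                                 measured=RomMeasurement(
                                     flexion=rom / 2, extension=rom / 2, rom=rom))
            jm = JointPainMap(participant_id=f"p{i}", week=1,
                              scores={"right_wrist": 2})
            recs.append(make_record(f"p{i}", joint_maps=[jm],
                                    rom_sessions=[session]))
        boxes = rom_pain_association(recs, week=1, side="right")
        assert len(boxes) == 1
        b = boxes[0]
        assert (b.severity, b.n) == (2, 3)
        assert (b.median, b.minimum, b.maximum) == (110.0, 100.0, 120.0)
        assert b.minimum <= b.q1 <= b.median <= b.q3 <= b.maximum

    def test_requires_both_map_and_measurement(self):
        session = RomSession(week=1, true_flexion=55, true_extension=55,
                             trace_seed=0)   # not measured
        rec = make_record("p0", rom_sessions=[session],
                          joint_maps=[JointPainMap(participant_id="p0",
                                                   week=1, scores={})])
        assert rom_pain_association([rec]) == []


class TestPreference:
    def test_study_marginals(self, study_marginal_records):
        df = preference_summary(study_marginal_records).set_index("preference")
        assert df.loc["app", "pct"] == 73.2
        assert df.loc["clinic", "pct"] == 3.0
        assert df.loc["both", "pct"] == 13.8
        assert df.n.sum() == 399

    def test_all_app(self):
        recs = [make_record(f"p{i}", preference="app") for i in range(7)]
        df = preference_summary(recs).set_index("preference")
        assert df.loc["app", "pct"] == 100.0

    def test_matches_brute_tally(self):
        records, _ = generate_cohort(CohortConfig(n_downloads=200, seed=5))
        df = preference_summary(records).set_index("preference")
        for choice in ("app", "clinic", "both", "none", "missing"):
            assert df.loc[choice, "n"] == sum(
                1 for r in records if r.preference == choice)
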