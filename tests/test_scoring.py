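import math
import random

import pytest

from _oracles import oracle_positioning, oracle_substantiation, random_pathway
from pathforge.engine import Cohort
from pathforge.errors import ConfigError
from pathforge.scoring import (
    ScoringConfig,
    audit_surveillance,
    drop_ratio,
    max_biomarker_drop,
    overall_score,
    positioning_score,
    score_cohort,
    score_pathway,
    substantiation,
)


class TestPositioning:
    def test_reference_pathway_has_readings_both_sides(self, reference_pathway):
        assert positioning_score(reference_pathway) == 3

    def test_no_readings(self, make_pathway):
        assert positioning_score(make_pathway([(0, "D", "2"), (10, "H", "x")])) == 0

    def test_reading_before_only(self, make_pathway):
        pw = make_pathway([(-10, "P", "8"), (0, "D", "2"), (5, "H", "x")])
        assert positioning_score(pw) == 1

    def test_reading_after_only(self, make_pathway):
        pw = make_pathway([(0, "H", "x"), (100, "P", "1")])
        assert positioning_score(pw) == 2

    def test_no_treatment_scores_one(self, make_pathway):
        pw = make_pathway([(-10, "P", "8"), (0, "D", "2"), (100, "P", "9")])
        assert positioning_score(pw) == 1

    def test_reading_at_treatment_time_counts_as_before(self, make_pathway):
        pw = make_pathway([(5, "H", "x"), (5, "P", "8"), (50, "P", "1")])
        assert positioning_score(pw) == 3

    def test_surveillance_is_not_a_positioning_reference(self, make_pathway):
        pw = make_pathway([(-10, "P", "8"), (5, "W", "surveillance"), (50, "P", "9")])
        assert positioning_score(pw) == 1


class TestMaxDrop:
    def test_reference_drop_is_first_collapse(self, reference_pathway):
        drop = max_biomarker_drop(reference_pathway)
        assert (drop.start.time, drop.end.time) == (-28, 260)
        assert drop.magnitude == pytest.approx(44.8)

    def test_rising_trend_has_no_drop(self, make_pathway):
        pw = make_pathway([(0, "P", "1"), (10, "P", "2"), (20, "P", "3")])
        assert max_biomarker_drop(pw) is None

    def test_single_reading(self, make_pathway):
        assert max_biomarker_drop(make_pathway([(0, "P", "1")])) is None

    def test_tie_breaks_to_earliest(self, make_pathway):
        pw = make_pathway([(0, "P", "10"), (10, "P", "5"), (20, "P", "10"), (30, "P", "5")])
        drop = max_biomarker_drop(pw)
        assert (drop.start.time, drop.end.time) == (0, 10)

    def test_all_pairs_mode_spans_nonadjacent_readings(self, make_pathway):
        pw = make_pathway([(0, "P", "10"), (10, "P", "6"), (20, "P", "1")])
        consecutive = max_biomarker_drop(pw)
        every = max_biomarker_drop(pw, ScoringConfig(pair_mode="all"))
        assert consecutive.magnitude == pytest.approx(5.0)
        assert every.magnitude == pytest.approx(9.0)
        assert (every.start.time, every.end.time) == (0, 20)


class TestSubstantiation:
    def test_reference_drop_explained_by_treatment(self, reference_pathway):
        assert substantiation(reference_pathway) == "yes"

    def test_unexplained_drop(self, make_pathway):
        # H precedes both readings, so it is outside the drop interval.
        pw = make_pathway([(-5, "H", "x"), (0, "P", "50"), (100, "P", "5")])
        assert substantiation(pw) == "no"

    def test_constant_trend_counts_as_substantiated(self, make_pathway):
        pw = make_pathway([(-5, "H", "x"), (0, "P", "2"), (50, "P", "2")])
        assert positioning_score(pw) == 2
        assert substantiation(pw) == "yes"

    def test_too_few_readings(self, make_pathway):
        pw = make_pathway([(0, "H", "x"), (10, "P", "3")])
        assert substantiation(pw) == "not_applicable"

    def test_low_positioning_is_not_applicable(self, make_pathway):
        pw = make_pathway([(-20, "P", "9"), (-10, "P", "4"), (0, "H", "x")])
        assert substantiation(pw) == "not_applicable"

    def test_interval_endpoints_inclusive(self, make_pathway):
        # surgery concurrent with the end of the max-drop interval still counts
        pw = make_pathway(
            [(0, "P", "50"), (100, "P", "5"), (100, "S", "op"), (150, "P", "4")]
        )
        assert substantiation(pw) == "yes"


class TestOverallScore:
    @pytest.mark.parametrize(
        "positioning, verdict, expected",
        [
            (0, "not_applicable", "S0"),
            (1, "not_applicable", "S1"),
            (2, "not_applicable", "S2"),
            (2, "no", "S2"),
            (3, "no", "S3"),
            (2, "yes", "S4"),
            (3, "yes", "S5"),
        ],
    )
    def test_mapping(self, positioning, verdict, expected):
        assert overall_score(positioning, verdict) == expected

    @pytest.mark.parametrize(
        "positioning, verdict",
        [(0, "yes"), (1, "no"), (3, "not_applicable"), (4, "yes"), (2, "maybe")],
    )
    def test_inconsistent_inputs_rejected(self, positioning, verdict):
        with pytest.raises(ConfigError):
            overall_score(positioning, verdict)


class TestDropRatio:
    def test_reference_ratio(self, reference_pathway):
        assert drop_ratio(reference_pathway) == pytest.approx(44.8 / 45, abs=1e-9)

    def test_rising_trend(self, make_pathway):
        pw = make_pathway([(0, "P", "1"), (10, "P", "2")])
        assert drop_ratio(pw) is None

    def test_simple_arithmetic(self, make_pathway):
        pw = make_pathway([(0, "P", "60"), (10, "H", "x"), (50, "P", "30")])
        assert drop_ratio(pw) == pytest.approx(0.5)

    def test_anchor_falls_back_to_first_post_diagnosis_reading(self, make_pathway):
        pw = make_pathway([(5, "P", "40"), (10, "H", "x"), (50, "P", "10")])
        assert drop_ratio(pw) == pytest.approx(30 / 40)


class TestOracleEquivalence:
    def test_positioning_and_substantiation_match_enumeration(self):
        rng = random.Random(20240901)
        for _ in range(2000):
            pw = random_pathway(rng)
            assert positioning_score(pw) == oracle_positioning(pw)
            assert substantiation(pw) == oracle_substantiation(pw)

    def test_low_positioning_never_substantiated(self):
        rng = random.Random(7)
        for _ in range(2000):
            pw = random_pathway(rng)
            rec = score_pathway(pw)
            if rec.positioning <= 1:
                assert rec.substantiation == "not_applicable"

    def test_scores_ignore_unrelated_activities(self, dictionary, make_pathway):
        from pathforge.core import Activity, Pathway

        rng = random.Random(99)
        for _ in range(200):
            pw = random_pathway(rng)
            noise = tuple(
                Activity("r", rng.randint(-50, 600), code, "v")
                for code in ("I", "X", "G")
            )
            noisy = Pathway("r", tuple(sorted(pw.activities + noise, key=lambda a: (a.time, a.code))))
            before, after = score_pathway(pw), score_pathway(noisy)
            assert (after.positioning, after.substantiation, after.overall) == (
                before.positioning, before.substantiation, before.overall,
            )


class TestCohortScoring:
    @pytest.fixture()
    def planted_cohort(self, dictionary, make_pathway):
        plants = {
            "s0": [(0, "D", "2"), (10, "H", "x")],
            "s1": [(-10, "P", "8"), (0, "D", "2"), (10, "H", "x")],
            "s2": [(0, "D", "2"), (10, "H", "x"), (50, "P", "1")],
            "s3": [(-10, "P", "8"), (5, "H", "x"), (40, "P", "7"), (80, "P", "1")],
            "s4": [(0, "D", "2"), (5, "H", "x"), (40, "P", "9"), (60, "S", "op"), (90, "P", "1")],
            "s5": [(-10, "P", "8"), (5, "H", "x"), (40, "P", "1")],
        }
        pathways = {pid: make_pathway(acts, pid=pid) for pid, acts in plants.items()}
        return Cohort(pathways=pathways, dictionary=dictionary)

    def test_one_pathway_per_class(self, planted_cohort):
        scores = score_cohort(planted_cohort)
        assert {pid: rec.overall for pid, rec in scores.records.items()} == {
            "s0": "S0", "s1": "S1", "s2": "S2", "s3": "S3", "s4": "S4", "s5": "S5",
        }
        assert list(scores.frequencies["count"]) == [1] * 6
        assert sum(scores.frequencies["count"]) == len(planted_cohort)

    def test_frequencies_sum_to_cohort_size(self, planted_cohort):
        scores = score_cohort(planted_cohort)
        assert scores.frequencies["fraction"].sum() == pytest.approx(1.0)

    def test_mean_unique_codes_per_class(self, planted_cohort):
        scores = score_cohort(planted_cohort)
        by_level = dict(zip(scores.frequencies["score"], scores.frequencies["mean_unique_codes"]))
        assert by_level["S0"] == 2.0  # D, H
        assert by_level["S4"] == 4.0  # D, H, P, S

    def test_empty_cohort(self, dictionary):
        scores = score_cohort(Cohort(pathways={}, dictionary=dictionary))
        assert scores.records == {}
        assert list(scores.frequencies["count"]) == [0] * 6


class TestSurveillanceAudit:
    def test_hidden_treatment_flagged_at_both_thresholds(self, dictionary, make_pathway):
        # PSA rises on surveillance then collapses to 0.5 with nothing recorded:
        # max drop 24.5 against a diagnosis PSA of 10 gives ratio 2.45.
        hidden = make_pathway(
            [(0, "P", "10"), (5, "W", "surv"), (100, "P", "25"), (200, "P", "0.5")],
            pid="hidden",
        )
        flat = make_pathway(
            [(0, "P", "6"), (5, "W", "surv"), (200, "P", "6.1")], pid="flat"
        )
        left = make_pathway(
            [(0, "P", "10"), (5, "W", "surv"), (100, "H", "x"), (200, "P", "0.5")],
            pid="left",
        )
        cohort = Cohort(
            pathways={"hidden": hidden, "flat": flat, "left": left},
            dictionary=dictionary,
        )
        table = audit_surveillance(cohort)
        assert sorted(table.patient_id) == ["flat", "hidden"]  # 'left' exited surveillance
        row = table.set_index("patient_id").loc["hidden"]
        assert row["over_0.5"] and row["over_1"]
        flat_row = table.set_index("patient_id").loc["flat"]
        assert not flat_row["over_0.5"] and math.isnan(flat_row["drop_ratio"])

    def test_no_surveillance_patients(self, reference_pathway, dictionary):
        cohort = Cohort(pathways={"1": reference_pathway}, dictionary=dictionary)
        assert len(audit_surveillance(cohort)) == 0
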