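import json

import pandas as pd
import pytest

from pathforge.core import default_dictionary, sort_master
from pathforge.dictionary import (
    ElementDecision,
    ElementFile,
    SplitSpec,
    apply_decision,
    ingest_element,
    load_decisions,
    read_element,
    update_master,
)
from pathforge.errors import ConfigError

WINDOW = ("2004-01-01", "2011-12-31")
DIAGNOSES = {"1": "2005-04-01", "2": "2005-06-01", "3": "2006-01-10"}


def element(code, rows, source="LAB"):
    return ElementFile(
        code=code,
        source_tag=source,
        rows=pd.DataFrame(rows, columns=["Identifier", "Date", "Value"]),
    )


class TestIngestElement:
    def test_censored_value_substituted(self):
        psa = element("P", [("1", "2005-05-01", "<0.1")])
        tuples, summary = ingest_element(psa, WINDOW, DIAGNOSES)
        assert list(tuples.Value) == ["0.05"]
        assert list(tuples.Time) == [30]
        assert summary.total_support == 1

    def test_window_exclusion_counted(self):
        psa = element("P", [("1", "2003-05-01", "4"), ("1", "2005-05-01", "5")])
        tuples, summary = ingest_element(psa, ("2004-01-01", "2011-12-31"), DIAGNOSES)
        assert len(tuples) == 1
        assert summary.excluded_window == 1

    def test_duplicates_dropped_and_counted(self):
        psa = element("P", [("1", "2005-05-01", "5")] * 3)
        tuples, summary = ingest_element(psa, WINDOW, DIAGNOSES)
        assert len(tuples) == 1
        assert summary.duplicates_dropped == 2

    def test_range_counts_on_three_patient_fixture(self):
        # 5 PSA rows over 3 patients, exactly one above the 4.0 ng/ml cut.
        psa = element(
            "P",
            [
                ("1", "2005-03-01", "2.1"),
                ("1", "2005-05-01", "3.0"),
                ("2", "2005-07-01", "6.5"),
                ("3", "2006-02-01", "1.2"),
                ("3", "2006-03-01", "0.8"),
            ],
        )
        _, summary = ingest_element(psa, WINDOW, DIAGNOSES, ranges={">4.0": ">4.0"})
        assert summary.range_counts == {">4.0": 1}
        assert summary.total_support == 3
        assert summary.extremes == (0.8, 6.5)

    def test_categorical_value_support(self):
        grade = element("G", [("1", "2005-04-02", "4+3"), ("2", "2005-06-02", "3+4")])
        _, summary = ingest_element(grade, WINDOW, DIAGNOSES)
        assert summary.value_support == {"3+4": 1, "4+3": 1}

    def test_sidecar_round_trip(self, tmp_path):
        csv = tmp_path / "psa.csv"
        csv.write_text("Identifier,Date,Value\n1,2005-05-01,4.2\n")
        (tmp_path / "psa.json").write_text(json.dumps({"code": "P", "source": "LAB"}))
        loaded = read_element(csv)
        assert loaded.code == "P" and loaded.source_tag == "LAB"
        assert len(loaded.rows) == 1


class TestApplyDecision:
    @pytest.fixture()
    def surgery_tuples(self):
        return pd.DataFrame(
            [
                ("1", 10, "S", "prostatectomy"),
                ("2", 12, "S", "orchidectomy"),
                ("3", 20, "S", "prostatectomy"),
            ],
            columns=["Identifier", "Time", "Code", "Value"],
        )

    @pytest.fixture()
    def reduced_dictionary(self):
        d = default_dictionary()
        d.remove("O")  # the split target must be a fresh code
        return d

    def test_split_surgery_into_orchidectomy(self, surgery_tuples, reduced_dictionary):
        decision = ElementDecision(
            code="S",
            verdict="split",
            split=SplitSpec(predicate="orchidectomy", new_code="O", new_name="Orchidectomy"),
        )
        out, updated = apply_decision(surgery_tuples, decision, reduced_dictionary)
        assert sorted(out.Code) == ["O", "S", "S"]
        assert "O" in updated
        assert updated["O"].clinical_class == "treatment"
        assert "O" not in reduced_dictionary  # original untouched

    def test_split_collision_rejected(self, surgery_tuples):
        decision = ElementDecision(
            code="S",
            verdict="split",
            split=SplitSpec(predicate="orchidectomy", new_code="O", new_name="Orchidectomy"),
        )
        with pytest.raises(ConfigError):
            apply_decision(surgery_tuples, decision, default_dictionary())

    def test_reject_leaves_no_trace(self, surgery_tuples, reduced_dictionary):
        out, updated = apply_decision(
            surgery_tuples, ElementDecision(code="S", verdict="reject"), reduced_dictionary
        )
        assert len(out) == 0
        assert "S" not in updated

    def test_keep_is_identity(self, surgery_tuples, reduced_dictionary):
        out, updated = apply_decision(
            surgery_tuples, ElementDecision(code="S", verdict="keep"), reduced_dictionary
        )
        assert out.equals(surgery_tuples)
        assert updated is reduced_dictionary

    def test_decision_contract(self):
        with pytest.raises(ConfigError):
            ElementDecision(code="S", verdict="split")  # split without a spec
        with pytest.raises(ConfigError):
            ElementDecision(code="S", verdict="maybe")

    def test_decisions_json_loader(self, tmp_path):
        path = tmp_path / "decisions.json"
        path.write_text(
            json.dumps(
                [
                    {"code": "P", "verdict": "keep"},
                    {
                        "code": "S",
                        "verdict": "split",
                        "split": {"predicate": "orchidectomy", "new_code": "O"},
                        "rationale": "distinct biomarker impact",
                    },
                ]
            )
        )
        keep, split = load_decisions(path)
        assert keep.verdict == "keep"
        assert split.split.new_code == "O"


class TestUpdateMaster:
    def master(self, rows):
        return pd.DataFrame(rows, columns=["Identifier", "Time", "Code", "Value"])

    def test_merge_is_idempotent(self):
        base = self.master([("1", 0, "D", "2"), ("1", 30, "P", "4.2")])
        d = default_dictionary()
        merged = update_master(base, base.copy(), d)
        assert merged.equals(sort_master(base))

    def test_support_fraction_recomputed(self):
        # 1904 patients with a diagnosis row; 1814 also have a PSA row.
        diag = self.master([(f"{i:05d}", 0, "D", "2") for i in range(1904)])
        psa = self.master([(f"{i:05d}", 30, "P", "5.0") for i in range(1814)])
        d = default_dictionary()
        merged = update_master(diag, psa, d)
        assert d["P"].support_count == 1814
        assert d["P"].support_fraction == pytest.approx(1814 / 1904)
        assert f"{d['P'].support_fraction:.2%}" == "95.27%"
        assert d["D"].support_fraction == 1.0
        assert len(merged) == 1904 + 1814

    def test_new_code_support_transitions_from_zero(self):
        d = default_dictionary()
        assert d["I"].support_count == 0
        base = self.master([("1", 0, "D", "2")])
        update_master(base, self.master([("1", 10, "I", "MRI")]), d)
        assert d["I"].support_count == 1
        assert d["I"].support_fraction == 1.0

    def test_ingestion_order_insensitive(self):
        psa = element("P", [("1", "2005-05-01", "4.0"), ("2", "2005-07-01", "9.9")])
        grade = element("G", [("1", "2005-04-02", "4+3")])
        finals = []
        for order in ([psa, grade], [grade, psa]):
            d = default_dictionary()
            master = self.master([])
            for el in order:
                tuples, _ = ingest_element(el, WINDOW, DIAGNOSES)
                master = update_master(master, tuples, d)
            finals.append(master)
        assert finals[0].equals(finals[1])
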