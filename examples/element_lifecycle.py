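"""Grow the master table one data element at a time.

Walks the element lifecycle for a PSA extract: ingest (window filter,
de-duplication, canonicalization, time zeroing, summary statistics), a
recorded keep/split decision, and the merge into the master table with
dictionary support refreshed.  A surgery element is split so orchidectomy
gets its own code, mirroring how qualitatively mixed elements are decomposed.
"""

import pandas as pd

from pathforge import (
    ElementDecision,
    ElementFile,
    SplitSpec,
    apply_decision,
    default_dictionary,
    ingest_element,
    update_master,
)

diagnoses = {"1": "2005-04-01", "2": "2005-06-01"}
window = ("2004-01-01", "2011-12-31")
dictionary = default_dictionary()
dictionary.remove("O")  # pretend orchidectomy is not yet a code

psa = ElementFile(
    code="P",
    source_tag="LAB",
    rows=pd.DataFrame(
        [
            ("1", "2005-03-04", "45"),
            ("1", "2005-12-16", "0.2"),
            ("1", "2005-12-16", "0.2"),  # duplicate row from a re-extract
            ("2", "2005-07-01", "<0.1"),  # below the assay limit
            ("2", "2002-01-01", "3.1"),  # before the study window
        ],
        columns=["Identifier", "Date", "Value"],
    ),
)
tuples, summary = ingest_element(psa, window, diagnoses, ranges={">4.0": ">4.0"})
print(f"PSA: kept {summary.n_rows} rows, excluded {summary.excluded_window} "
      f"(window) + {summary.duplicates_dropped} (duplicates); "
      f"support {summary.total_support} patients; raised (>4.0): "
      f"{summary.range_counts['>4.0']}")

surgery = ElementFile(
    code="S",
    source_tag="OT",
    rows=pd.DataFrame(
        [("1", "2005-04-20", "prostatectomy"), ("2", "2005-06-20", "orchidectomy")],
        columns=["Identifier", "Date", "Value"],
    ),
)
surgery_tuples, _ = ingest_element(surgery, window, diagnoses)
split = ElementDecision(
    code="S",
    verdict="split",
    split=SplitSpec(predicate="orchidectomy", new_code="O", new_name="Orchidectomy"),
    rationale="orchidectomy affects the biomarker differently",
)
surgery_tuples, dictionary = apply_decision(surgery_tuples, split, dictionary)

master = pd.DataFrame(columns=["Identifier", "Time", "Code", "Value"])
for element_tuples in (tuples, surgery_tuples):
    master = update_master(master, element_tuples, dictionary)

print(master.to_string(index=False))
for code in ("P", "S", "O"):
    entry = dictionary[code]
    print(f"support[{code}] = {entry.support_count} ({entry.support_fraction:.0%})")

# The censored '<0.1' arrives in the master as 0.05; the orchidectomy row now
# carries code O, and per-code support reflects the merged table.
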