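"""Cohort summary statistics and regular-expression pathway retrieval.

Simulates a small cohort, prints the standard pathway statistics (lengths,
common codes, collapsed sequences, treatment regimes) and retrieves patients
whose collapsed code sequence matches a pattern.
"""

import json

from pathforge import Cohort, SimulationConfig, cohort_summary, query, simulate_cohort

master, _ = simulate_cohort(SimulationConfig(n_patients=300, seed=5))
cohort = Cohort.from_master(master)

summary = cohort_summary(cohort, window_days=92)
print(json.dumps(summary.to_dict(), indent=2))

# Patients whose (collapsed) sequence shows PSA, then surgery, then PSA again
# — i.e. biomarker follow-up around an operation:
hits = query(cohort, "P.*S.*P")
print(f"\n{len(hits)} patients match P.*S.*P, e.g. {hits[:5]}")

# Treatment regimes group the first treatment modality with any different
# modality begun within 92 days; 'H' alone dominates, as configured.
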